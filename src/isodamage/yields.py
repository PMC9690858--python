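"""Analytical DNA-damage yield curves and the fitted parameter registry.

Yield curves give the induction of DNA lesions in a human lymphocyte
nucleus, normalized per gray of nucleus dose and per gigabase pair of
genome, as a function of the ion's starting energy per nucleon.  Four
damage classes are distinguished:

* ``SSB`` - single-strand breaks;
* ``DSB_SITES`` - genomic sites carrying either an isolated double-strand
  break or a cluster of them (a cluster counts once);
* ``DSB_CLUSTERS`` - groups of two or more DSB within 25 bp;
* ``DSB_TOTAL`` - all DSB, counting every member of a cluster.

Each registry row holds nine fitted parameters ``p0..p8``.  ``p0`` sets
the high-energy yield level; ``p1, p2, p3`` shape a logistic suppression
term in log energy; ``p4..p8`` modulate that term's slope exponent
through a second sigmoid.  The algebraic composition implemented here is

    Y(E) = p0 + p1*E^p2 / (1 + exp(p3) * E^(p2 + q(E))),
    q(E) = sign(p4)*|p4|^p7 / (1 + exp(p5)*E^p6)^p8.

The printed source of this nine-parameter expression is typographically
ambiguous; this composition is the reading that is finite, real and
positive for every registry row on its validity domain and reproduces
the high-energy yield anchors.  See docs/methods.md for the full
discussion of the ambiguity and its consequences; the signed power
``sign(p4)*|p4|^p7`` is an explicit, documented choice for the one row
with a negative ``p4`` and non-integer ``p7``.

Hydrogen and helium isotopes have per-isotope parameter rows; for
lithium through carbon a single row per element suffices (isotope
differences are negligible once yields are normalized per dose).  Rows
for the non-SSB damage classes of Li-C were published elsewhere and are
not bundled; the registry is user-extensible through JSON so they can be
registered without code changes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import IsotopeSpec, parse_isotope
from .dosimetry import GeometryConfig, disk_averaged_deposition

__all__ = [
    "DamageClass",
    "Eq1Params",
    "RegistryError",
    "builtin_registry",
    "select_params",
    "eval_yield",
    "isolated_dsb",
    "mean_cluster_multiplicity",
    "per_track_yield",
    "paper_energy_grid",
    "poisson_relative_sd",
    "yield_table",
    "registry_to_json",
    "registry_from_json",
    "registry_checksum",
    "DEFAULT_GENOME_GBP",
]

#: default genome length, Gbp (diploid human)
DEFAULT_GENOME_GBP = 6.6


class DamageClass(str, Enum):
    SSB = "SSB"
    DSB_SITES = "DSB_SITES"
    DSB_CLUSTERS = "DSB_CLUSTERS"
    DSB_TOTAL = "DSB_TOTAL"


class RegistryError(KeyError):
    """A (damage class, species) pair has no registered parameter row."""


@dataclass(frozen=True)
class Eq1Params:
    """One fitted yield-curve parameter row.

    ``scope`` is an isotope label ("2H") for H/He or an element symbol
    ("C") for heavier species.  ``valid_energy`` is the inclusive energy
    window (MeV/u) over which the row represents the simulations:
    0.1-512 for hydrogen and helium, 0.25-512 otherwise.
    """

    damage_class: DamageClass
    scope: str
    p0: float
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float = 1.0
    p8: float = 1.0

    @property
    def valid_energy(self) -> tuple[float, float]:
        # per-isotope scopes (H/He, digit-prefixed) extend down to 0.1 MeV/u
        if any(ch.isdigit() for ch in self.scope):
            return (0.1, 512.0)
        return (0.25, 512.0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p0, self.p1, self.p2, self.p3, self.p4, self.p5, self.p6,
             self.p7, self.p8]
        )


def _row(cls, scope, *p) -> Eq1Params:
    if len(p) == 7:
        p = (*p, 1.0, 1.0)
    return Eq1Params(DamageClass(cls), scope, *p)


# Fitted parameters, transcribed verbatim from the published table.
_BUILTIN_ROWS: tuple[Eq1Params, ...] = (
    _row("SSB", "3H", 156, -24.93, -0.3641, -6.929, -6.011, -6.255, -6.115),
    _row("SSB", "2H", 156, -25.31, -0.3800, -6.719, -7.741, -6.305, -7.999),
    _row("SSB", "1H", 156, -25.94, -0.3725, -4.438, -8.884, -4.152, -9.307),
    _row("SSB", "4He", 156, -49.45, -0.4011, -1.353, -3.763, -0.7219, -3.719),
    _row("SSB", "3He", 156, -48.02, -0.3839, -0.6727, -4.131, -0.07540, -4.142),
    _row("SSB", "Li", 156, -41.32, -0.2756, -1.375, -1.316, 0.2535, -0.9409),
    _row("SSB", "Be", 156, -22.54, -0.1273, -1.359, -1.136, 1.388, -0.6218),
    _row("SSB", "B", 156, -4.762, 0.1012, -1.214, -1.121, 3.253, -0.6463),
    _row("SSB", "C", 156, -3.197, 0.1951, -0.2466, -1.018, 4.076, -0.7828),
    _row("DSB_SITES", "3H", 6.8, 632.3, 2.302, 4.961, 0.7071, -4.408, -2.148),
    _row("DSB_SITES", "2H", 6.8, 321.9, 2.529, 4.327, 0.6768, -2.627, -1.894),
    _row("DSB_SITES", "1H", 6.8, 69.50, 2.468, 3.406, 0.4781, 0.2036, -0.9876),
    _row("DSB_SITES", "4He", 6.8, 6.288, 0.3915, 0.06198, 0.8175, 0.7250, 1.052e-4),
    _row("DSB_SITES", "3He", 6.8, 7.374, 0.5449, 0.3136, 0.7952, 0.7243, -2.555e-5),
    _row("DSB_CLUSTERS", "3H", 0.07, 61.58, 3.110, 6.153, 1.421, -3.013, -2.496),
    _row("DSB_CLUSTERS", "2H", 0.07, 9.363, 3.088, 4.606, 0.9136, -0.6496, -2.212),
    _row("DSB_CLUSTERS", "1H", 0.07, 0.2697, 3.691, 3.106, 0.2513, 2.557, -2.827),
    _row("DSB_CLUSTERS", "4He", 0.07, 4.605, 1.721, 1.803, 1.089, 0.07841, -1.110),
    _row("DSB_CLUSTERS", "3He", 0.07, 1.791, 1.989, 1.407, 0.9043, 1.159, -1.284),
    _row("DSB_TOTAL", "3H", 6.8, 37.22, 0.6415, 7.099, 4.083, -5.500, 2.588, 0.2926, 0.1174),
    _row("DSB_TOTAL", "2H", 6.8, 42.81, 0.8008, 5.279, 3.209, 0.8288, 1.586, 0.5030, 0.3777),
    _row("DSB_TOTAL", "1H", 6.8, 473.1, 2.028, 1.682, -0.3444, -0.9622, 4.825, 2.515, 0.3132),
    _row("DSB_TOTAL", "4He", 6.8, 10.56, 0.6902, 1.331, 0.8017, 1.317, 3.769e-5, 0.9350, 0.9792),
    _row("DSB_TOTAL", "3He", 6.8, 9.604, 0.6996, 1.425, 1.220, 1.318, 7.779e-5, 0.7288, 0.8862),
)

#: external reference that publishes the missing Li-C rows for DSB classes
_EXTERNAL_SOURCE_HINT = (
    "element-level parameters for the DSB damage classes of Li-C were "
    "published separately and are not bundled; register them via "
    "registry_from_json()/register_params()"
)


def builtin_registry() -> dict[tuple[DamageClass, str], Eq1Params]:
    """The built-in registry keyed by (damage class, scope)."""
    return {(r.damage_class, r.scope): r for r in _BUILTIN_ROWS}


_USER_ROWS: dict[tuple[DamageClass, str], Eq1Params] = {}


def register_params(params: Eq1Params) -> None:
    """Register (or override) a parameter row for this session."""
    _USER_ROWS[(params.damage_class, params.scope)] = params


def select_params(damage_class, iso) -> Eq1Params:
    """Resolve the parameter row for a damage class and species.

    Hydrogen and helium resolve per isotope; lithium through carbon per
    element.  Missing rows raise :class:`RegistryError` with a hint at
    the external parameter source.
    """
    damage_class = DamageClass(damage_class)
    if isinstance(iso, str):
        iso = parse_isotope(iso)
    reg = builtin_registry()
    reg.update(_USER_ROWS)
    scope = iso.label if iso.Z <= 2 else iso.element
    try:
        return reg[(damage_class, scope)]
    except KeyError:
        raise RegistryError(
            f"no parameters for ({damage_class.value}, {scope}): "
            + _EXTERNAL_SOURCE_HINT
        ) from None


def eval_yield(params: Eq1Params, e_per_u, *, clamp: bool = False):
    """Evaluate a yield curve, per Gy per Gbp.

    Energies outside the row's validity window raise by default; with
    ``clamp=True`` they are clamped to the window boundary (useful when
    coupling to transport codes that track particles to stopping).
    """
    e = np.asarray(e_per_u, dtype=float)
    lo, hi = params.valid_energy
    if clamp:
        e = np.clip(e, lo, hi)
    elif np.any(e < lo * (1 - 1e-12)) or np.any(e > hi * (1 + 1e-12)):
        raise ValueError(
            f"energy outside validity window [{lo}, {hi}] MeV/u for "
            f"({params.damage_class.value}, {params.scope}); pass clamp=True "
            "to clamp"
        )
    p = params
    with np.errstate(over="ignore"):
        shift = np.sign(p.p4) * abs(p.p4) ** p.p7 / (
            1.0 + np.exp(p.p5) * e**p.p6
        ) ** p.p8
        denom = 1.0 + np.exp(p.p3) * e ** (p.p2 + shift)
        y = p.p0 + p.p1 * e**p.p2 / denom
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(
            f"non-finite yield for ({p.damage_class.value}, {p.scope})"
        )
    return y if e.ndim else float(y)


# --- derived damage metrics --------------------------------------------------


def isolated_dsb(sites, clusters):
    """Isolated-DSB yield: sites minus clusters (same units)."""
    sites = np.asarray(sites, dtype=float)
    clusters = np.asarray(clusters, dtype=float)
    if np.any(clusters < 0) or np.any(sites < 0):
        raise ValueError("yields must be nonnegative")
    if np.any(clusters > sites):
        raise ValueError("cluster yield cannot exceed DSB-site yield")
    out = sites - clusters
    return out if out.ndim else float(out)


def mean_cluster_multiplicity(total, sites, clusters):
    """Mean number of DSB per cluster.

    Isolated DSB number ``sites - clusters``; the DSB contained in
    clusters therefore number ``total - (sites - clusters)``, and the
    mean multiplicity is ``(total - sites + clusters) / clusters``.
    """
    total = float(total)
    sites = float(sites)
    clusters = float(clusters)
    if clusters <= 0:
        raise ValueError("cluster yield must be positive (multiplicity undefined)")
    if total < sites:
        raise ValueError("total DSB cannot be below DSB sites")
    m = (total - sites + clusters) / clusters
    if m < 2.0:
        warnings.warn(
            "mean cluster multiplicity below 2 - degenerate input "
            "(every cluster should contain at least two DSB)",
            stacklevel=2,
        )
    return m


def per_track_yield(yield_per_gy_gbp, dose_per_track, genome_gbp=DEFAULT_GENOME_GBP):
    """Expected damage count per primary particle track.

    Product of the per-dose-per-length yield, the dose per track and the
    genome length; ratios between species at equal genome length cancel
    the genome factor.
    """
    y = np.asarray(yield_per_gy_gbp, dtype=float)
    d = np.asarray(dose_per_track, dtype=float)
    if np.any(y < 0) or np.any(d < 0) or genome_gbp < 0:
        raise ValueError("inputs must be nonnegative")
    out = y * d * genome_gbp
    return out if out.ndim else float(out)


def poisson_relative_sd(mean_total_count):
    """Relative standard deviation of a Poisson-scored total, 1/sqrt(N)."""
    n = np.asarray(mean_total_count, dtype=float)
    if np.any(n <= 0):
        raise ValueError("mean count must be positive")
    out = 1.0 / np.sqrt(n)
    return out if out.ndim else float(out)


# --- energy grids ------------------------------------------------------------

#: low-energy extension used for H and He isotopes
_LOW_E_EXTENSION = (0.1, 0.125, 0.15, 0.175, 0.2, 0.3, 0.35, 0.4, 0.5, 0.7)


def paper_energy_grid(iso) -> np.ndarray:
    """Simulation starting-energy grid for one species, MeV/u.

    Log-equidistant with a factor-2 step from 0.25 to 512 (12 values);
    hydrogen and helium prepend a denser low-energy extension starting
    at 0.1 MeV/u where isotope specificity is maximal.
    """
    if isinstance(iso, str):
        iso = parse_isotope(iso)
    base = 0.25 * 2.0 ** np.arange(12)
    if iso.Z <= 2:
        grid = np.unique(np.concatenate([np.asarray(_LOW_E_EXTENSION), base]))
    else:
        grid = base
    return grid


# --- joined tables -----------------------------------------------------------


def yield_table(
    isotopes,
    classes,
    geom: GeometryConfig,
    table,
    genome_gbp: float = DEFAULT_GENOME_GBP,
) -> pd.DataFrame:
    """One row per (species, grid energy): dosimetry joined with yields.

    Columns: species, E (MeV/u), nucleus-averaged LET (keV/µm), dose per
    track (Gy), then per damage class the per-Gy-per-Gbp yield and the
    per-track yield.  Keyed by energy; re-keying by LET is a column sort
    away (the LET-keyed view is not monotone at low energies - distal and
    proximal energies can share one LET).
    """
    classes = [DamageClass(c) for c in classes]
    rows = []
    for iso in isotopes:
        if isinstance(iso, str):
            iso = parse_isotope(iso)
        for e in paper_energy_grid(iso):
            summary = disk_averaged_deposition(iso, e, geom, table)
            row = {
                "species": iso.label,
                "E_MeV_u": float(e),
                "LET_keV_um": summary.nucleus_LET,
                "dose_per_track_Gy": summary.dose_per_track,
            }
            for cls in classes:
                p = select_params(cls, iso)
                y = eval_yield(p, e)
                row[f"{cls.value}_per_Gy_Gbp"] = y
                row[f"{cls.value}_per_track"] = per_track_yield(
                    y, summary.dose_per_track, genome_gbp
                )
            rows.append(row)
    return pd.DataFrame(rows)


# --- registry I/O ------------------------------------------------------------


def _canonical_rows(registry) -> list[dict]:
    rows = []
    for (_, _), params in sorted(
        registry.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
    ):
        d = asdict(params)
        d["damage_class"] = params.damage_class.value
        rows.append(d)
    return rows


def registry_to_json(path, registry=None) -> None:
    """Dump a registry as JSON keyed by (class, scope)."""
    registry = registry if registry is not None else builtin_registry()
    payload = {
        "rows": _canonical_rows(registry),
        "checksum": registry_checksum(registry),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def registry_from_json(path, *, register: bool = False):
    """Load registry rows from JSON; optionally register them for selection."""
    payload = json.loads(Path(path).read_text())
    rows = {}
    for d in payload["rows"]:
        d = dict(d)
        d["damage_class"] = DamageClass(d["damage_class"])
        params = Eq1Params(**d)
        rows[(params.damage_class, params.scope)] = params
        if register:
            register_params(params)
    return rows


def registry_checksum(registry=None) -> str:
    """SHA-256 over the canonical JSON serialization of the registry."""
    registry = registry if registry is not None else builtin_registry()
    blob = json.dumps(_canonical_rows(registry), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
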