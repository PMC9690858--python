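"""Projectile identities: light-ion isotopes from hydrogen to carbon.

An ion's electromagnetic interactions in matter depend on its atomic
number (through the charge) and its velocity, i.e. its kinetic energy
per nucleon.  The mass number enters only kinematically: at equal
energy per nucleon a heavier isotope carries proportionally more total
energy and therefore penetrates further.  ``IsotopeSpec`` captures
exactly this (Z, A) identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["IsotopeSpec", "parse_isotope", "SUPPORTED_ISOTOPES", "ELEMENTS"]

#: element symbols indexed by atomic number (supported range)
ELEMENTS: dict[int, str] = {1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C"}
_Z_OF = {sym: z for z, sym in ELEMENTS.items()}

#: the isotope set the damage database covers
SUPPORTED_ISOTOPES: tuple[str, ...] = (
    "1H", "2H", "3H",
    "3He", "4He",
    "6Li", "7Li",
    "9Be", "10Be",
    "10B", "11B",
    "10C", "11C", "12C", "13C", "14C",
)

_LABEL_RE = re.compile(r"^(\d{1,3})([A-Z][a-z]?)$")

#: atomic mass of one nucleon used for relativistic kinematics, MeV/u
ATOMIC_MASS_MEV = 931.494


@dataclass(frozen=True, order=True)
class IsotopeSpec:
    """A projectile nucleus: atomic number ``Z`` and mass number ``A``."""

    Z: int
    A: int

    def __post_init__(self) -> None:
        if self.Z not in ELEMENTS:
            raise ValueError(
                f"unsupported atomic number Z={self.Z}; supported Z: "
                f"{sorted(ELEMENTS)} (H through C)"
            )
        if self.A < self.Z:
            raise ValueError(f"nonphysical mass number A={self.A} < Z={self.Z}")

    @property
    def element(self) -> str:
        return ELEMENTS[self.Z]

    @property
    def label(self) -> str:
        return f"{self.A}{self.element}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_isotope(label: str, *, strict: bool = True) -> IsotopeSpec:
    """Parse a mass-number-prefixed label such as ``"3He"`` or ``"14C"``.

    Parameters
    ----------
    label:
        Mass number followed by the element symbol (``"2H"``, ``"12C"``).
    strict:
        When true (default) only the isotopes of the built-in registry
        (:data:`SUPPORTED_ISOTOPES`) are accepted; when false any
        physically valid (Z, A) with Z in 1..6 parses.

    Returns
    -------
    IsotopeSpec

    Raises
    ------
    ValueError
        For unparseable strings, unsupported elements, A < Z, or (in
        strict mode) isotopes outside the supported registry.
    """
    if not isinstance(label, str):
        raise ValueError(f"isotope label must be a string, got {type(label)!r}")
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(
            f"cannot parse isotope label {label!r}; expected e.g. '2H', '12C'"
        )
    a_str, sym = m.groups()
    if sym not in _Z_OF:
        raise ValueError(f"unsupported element {sym!r}; supported: H, He, Li, Be, B, C")
    iso = IsotopeSpec(Z=_Z_OF[sym], A=int(a_str))
    if strict and iso.label not in SUPPORTED_ISOTOPES:
        raise ValueError(
            f"isotope {iso.label!r} is not in the supported registry "
            f"{SUPPORTED_ISOTOPES}; pass strict=False to allow it"
        )
    return iso


def beta_from_energy(e_per_u: float) -> float:
    """Speed ratio v/c of an ion at kinetic energy ``e_per_u`` (MeV/u).

    Relativistic kinematics with the nucleon rest mass 931.494 MeV/u:
    beta^2 = 1 - (1 + E/m)^/-2/.
    """
    import numpy as np

    e = np.asarray(e_per_u, dtype=float)
    if np.any(e < 0):
        raise ValueError("kinetic energy must be nonnegative")
    gamma = 1.0 + e / ATOMIC_MASS_MEV
    b2 = 1.0 - gamma**-2
    return np.sqrt(np.clip(b2, 0.0, 1.0))
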