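"""Refitting the nine-parameter yield formula to yield-vs-energy data.

The curve family is over-parameterized: distinct parameter vectors can
describe nearly identical curves, so the contract of this module is
*curve* recovery, not parameter recovery.  Fits hold ``p0`` (the
high-energy yield level, fixed externally) constant and optimize
``p1..p6`` - plus the exponents ``p7, p8`` for the total-DSB class - by
weighted least squares with multi-start perturbations around the
initialization.

``YieldCurveFitter`` is an sklearn-compatible estimator (fit/predict,
``get_params``/``set_params``) so it drops into sklearn model-selection
tooling; ``fit_eq1`` and ``simulate_yield_data`` are thin functional
wrappers matching the rest of the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .yields import DamageClass, Eq1Params, eval_yield, select_params

__all__ = [
    "FitDataset",
    "FitResult",
    "YieldCurveFitter",
    "simulate_yield_data",
    "fit_eq1",
]


@dataclass
class FitDataset:
    """Yield-vs-energy observations for one damage class and species."""

    energies: np.ndarray          # MeV/u, strictly positive
    yields: np.ndarray            # per Gy per Gbp
    sigma: np.ndarray | None      # standard deviations, same units
    damage_class: DamageClass
    species: str

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.energies.ndim != 1 or self.energies.size == 0:
            raise ValueError("need a nonempty 1-D energy grid")
        if np.any(self.energies <= 0):
            raise ValueError("energies must be strictly positive")
        if self.yields.shape != self.energies.shape:
            raise ValueError("yields must match the energy grid")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.energies.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive and match the grid")
        self.damage_class = DamageClass(self.damage_class)

    def to_frame(self) -> pd.DataFrame:
        d = {"E_MeV_u": self.energies, "Y_per_Gy_Gbp": self.yields}
        if self.sigma is not None:
            d["sigma"] = self.sigma
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, damage_class, species: str):
        sigma = frame["sigma"].to_numpy() if "sigma" in frame.columns else None
        return cls(
            frame["E_MeV_u"].to_numpy(),
            frame["Y_per_Gy_Gbp"].to_numpy(),
            sigma,
            DamageClass(damage_class),
            species,
        )


@dataclass
class FitResult:
    params: Eq1Params
    rmse: float                   # weighted root-mean-square residual, yield units
    curve_rel_error: float        # max relative curve error on the reference grid
    converged: bool
    n_restarts_used: int
    cost: float = field(default=np.nan)

    def to_json_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["params"]["damage_class"] = self.params.damage_class.value
        return d


def simulate_yield_data(
    params: Eq1Params,
    grid,
    noise_rel: float,
    seed: int | None = None,
) -> FitDataset:
    """Sample a registry curve with multiplicative Gaussian noise.

    ``Y_obs = Y(E) * (1 + noise_rel * N(0,1))``, with ``sigma`` recorded
    as ``noise_rel * Y``; reproducible under ``seed``.  This emulates the
    statistical scatter of Monte Carlo damage scoring (relative errors of
    a few percent), not its systematic features.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty energy grid")
    if noise_rel < 0:
        raise ValueError("noise_rel must be nonnegative")
    rng = np.random.default_rng(seed)
    truth = eval_yield(params, grid)
    noisy = truth * (1.0 + noise_rel * rng.standard_normal(grid.shape))
    sigma = noise_rel * truth if noise_rel > 0 else None
    return FitDataset(grid, noisy, sigma, params.damage_class, params.scope)


class YieldCurveFitter(BaseEstimator, RegressorMixin):
    """Weighted least-squares fitter for the yield-curve family.

    Parameters
    ----------
    damage_class:
        Class being fitted; decides whether the exponents ``p7, p8`` are
        free (total DSB) or pinned at 1.
    p0:
        Fixed high-energy yield level.  Refusing to free ``p0`` is part
        of the fitting contract.
    init:
        Optional :class:`Eq1Params` initialization; defaults to the
        registry row of the nearest species/class when resolvable, else
        magnitude heuristics.
    n_restarts:
        Multi-start perturbations (log-uniform within a factor 3 of the
        initialization), best-of returned.
    random_state:
        Seed making the restart sequence (and hence the result)
        deterministic.

    After ``fit``, ``params_`` holds the best row, ``result_`` the full
    :class:`FitResult`.
    """

    def __init__(
        self,
        damage_class: DamageClass = DamageClass.DSB_SITES,
        p0: float = 6.8,
        init: Eq1Params | None = None,
        n_restarts: int = 32,
        random_state: int | None = 0,
        log_space: bool = False,
    ):
        self.damage_class = damage_class
        self.p0 = p0
        self.init = init
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.log_space = log_space

    # -- internals -----------------------------------------------------------

    def _free_names(self):
        names = ["p1", "p2", "p3", "p4", "p5", "p6"]
        if DamageClass(self.damage_class) is DamageClass.DSB_TOTAL:
            names += ["p7", "p8"]
        return names

    def _init_params(self, species: str) -> Eq1Params:
        if self.init is not None:
            return replace(
                self.init, p0=self.p0, damage_class=DamageClass(self.damage_class)
            )
        try:
            row = select_params(self.damage_class, species)
            return replace(row, p0=self.p0)
        except Exception:
            return Eq1Params(
                DamageClass(self.damage_class), species, self.p0,
                p1=10.0, p2=1.0, p3=1.0, p4=0.5, p5=0.0, p6=-1.0,
            )

    def _model(self, theta, names, base: Eq1Params, e):
        params = replace(base, **dict(zip(names, theta)))
        with np.errstate(all="ignore"):
            shift = np.sign(params.p4) * abs(params.p4) ** params.p7 / (
                1.0 + np.exp(np.clip(params.p5, -700, 700)) * e**params.p6
            ) ** params.p8
            denom = 1.0 + np.exp(np.clip(params.p3, -700, 700)) * e ** (
                params.p2 + shift
            )
            y = params.p0 + params.p1 * e**params.p2 / denom
        return y

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, sample_weight=None, species: str = "1H"):
        """Fit to energies ``X`` (MeV/u) and yields ``y``.

        ``sample_weight`` follows the sklearn convention; when the data
        carry standard deviations use ``weight = 1/sigma**2``.
        """
        e = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        names = self._free_names()
        if e.size < len(names) + 1:
            raise ValueError(
                f"degenerate data: {e.size} points for {len(names)} free parameters"
            )
        if np.log10(e.max() / e.min()) < 2.0 and e.size >= 8:
            raise ValueError("data must span at least two decades of energy")
        if sample_weight is None:
            sigma = np.ones_like(y)
        else:
            w = np.asarray(sample_weight, dtype=float)
            sigma = 1.0 / np.sqrt(w)
        base = self._init_params(species)
        theta0 = np.array([getattr(base, n) for n in names])

        def residuals(theta):
            m = self._model(theta, names, base, e)
            if self.log_space:
                with np.errstate(all="ignore"):
                    r = np.log(np.abs(m) + 1e-12) - np.log(np.abs(y) + 1e-12)
            else:
                r = m - y
            r = r / sigma
            return np.where(np.isfinite(r), r, 1e6)

        rng = np.random.default_rng(self.random_state)
        best = None
        n_used = 0
        for k in range(max(1, int(self.n_restarts))):
            n_used += 1
            if k == 0:
                start = theta0
            else:
                factors = np.exp(rng.uniform(-np.log(3.0), np.log(3.0), theta0.size))
                start = theta0 * factors
                zero = np.abs(theta0) < 1e-12
                start[zero] = rng.uniform(-1.0, 1.0, zero.sum())
            try:
                sol = least_squares(residuals, start, method="lm", max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all restarts failed")
        fitted = replace(base, **dict(zip(names, best.x)))
        pred = self._model(best.x, names, base, e)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        rel = float(
            np.sqrt(np.mean(((pred - y) / np.maximum(np.abs(y), 1e-12)) ** 2))
        )
        self.params_ = fitted
        self.result_ = FitResult(
            params=fitted,
            rmse=rmse,
            curve_rel_error=rel,
            converged=bool(best.success),
            n_restarts_used=n_used,
            cost=float(best.cost),
        )
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        e = np.asarray(X, dtype=float).reshape(-1)
        names = self._free_names()
        theta = np.array([getattr(self.params_, n) for n in names])
        return self._model(theta, names, self.params_, e)


def fit_eq1(
    data: FitDataset,
    p0_fixed: float,
    damage_class=None,
    init: Eq1Params | None = None,
    n_restarts: int = 32,
    seed: int | None = 0,
    *,
    p0_free: bool = False,
    log_space: bool = False,
) -> FitResult:
    """Refit the curve family to a dataset with ``p0`` held fixed.

    Weighted (1/sigma^2) least squares over the free parameters with
    seeded multi-start; deterministic under ``seed``.  Requesting a free
    ``p0`` is rejected: the high-energy level is fixed by contract.
    """
    if p0_free:
        raise ValueError("p0 is fixed by contract and cannot be freed")
    damage_class = DamageClass(damage_class or data.damage_class)
    fitter = YieldCurveFitter(
        damage_class=damage_class,
        p0=p0_fixed,
        init=init,
        n_restarts=n_restarts,
        random_state=seed,
        log_space=log_space,
    )
    weight = None if data.sigma is None else 1.0 / data.sigma**2
    fitter.fit(data.energies, data.yields, sample_weight=weight, species=data.species)
    result = fitter.result_
    # relative curve error against the observations on their own grid
    pred = fitter.predict(data.energies)
    rel = float(
        np.sqrt(np.mean(((pred - data.yields) / np.maximum(np.abs(data.yields), 1e-12)) ** 2))
    )
    result.curve_rel_error = rel
    return result
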