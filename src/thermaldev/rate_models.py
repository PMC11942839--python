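"""Temperature-dependent development-rate models.

Two classical models for the development rate D(T) (1/day) of ectotherms
reared at constant temperature T (°C):

* the **linear** (degree-day) model ``D(T) = a + b*T``, whose x-intercept
  ``Tb = -a/b`` is the lower developmental threshold and whose reciprocal
  slope ``DD = 1/b`` is the thermal constant in degree-days;
* the **Brière** model ``D(T) = n * T * (T - Tb) * (TL - T)^(1/m)``, zero at
  both thermal thresholds Tb < TL, with an asymmetric peak at a closed-form
  optimum temperature.

Both are fitted by least squares; the Brière objective is multimodal in
(Tb, TL, m), so the fit uses a deterministic multistart grid with local
refinement (no randomness: fits are reproducible bit-for-bit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .lifetable_io import RateObservation

__all__ = [
    "LinearFitResult",
    "BriereFitResult",
    "BriereBounds",
    "FitError",
    "UndefinedResultError",
    "fit_linear",
    "linear_lower_threshold",
    "linear_degree_days",
    "briere_rate",
    "fit_briere",
    "briere_optimum",
    "r_squared",
]


class FitError(RuntimeError):
    """Raised when a model fit cannot be performed on the given data."""


class UndefinedResultError(ValueError):
    """Raised when a derived quantity (threshold, DD, R²) is undefined."""


# ---------------------------------------------------------------------------
# helpers

def _to_arrays(obs: Iterable[RateObservation]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = list(obs)
    t = np.array([o.temperature for o in obs], dtype=float)
    y = np.array([o.rate for o in obs], dtype=float)
    w = np.array([o.weight for o in obs], dtype=float)
    return t, y, w


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination R² = 1 - SSres/SStot.

    SStot is centred on the observed mean; the same formula is used for the
    linear and the nonlinear model (no adjustment for parameter count).

    Raises :class:`UndefinedResultError` when the observed values are all
    identical (SStot = 0).
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {f.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedResultError("R² undefined: observed values all identical")
    ss_res = float(np.sum((y - f) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# linear (degree-day) model

#: slopes at or below this (1/(day·°C)) are numerically indistinguishable
#: from zero; real insect fits sit around 1e-3
_B_TINY = 1e-12


@dataclass(frozen=True)
class LinearFitResult:
    """OLS fit of D(T) = a + b*T with derived thermal quantities.

    ``t_b`` (= -a/b) and ``dd`` (= 1/b) are derived from a and b at access
    time and are ``None`` when b <= 0, where the degree-day model has no
    biological interpretation.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    r2: float
    n_obs: int

    @property
    def t_b(self) -> float | None:
        return -self.a / self.b if self.b > _B_TINY else None

    @property
    def dd(self) -> float | None:
        return 1.0 / self.b if self.b > _B_TINY else None

    def predict(self, temperature):
        return self.a + self.b * np.asarray(temperature, dtype=float)


def fit_linear(obs: Iterable[RateObservation]) -> LinearFitResult:
    """Weighted ordinary least squares of rate on temperature.

    Observation weights (cell n for expanded group means, 1 for individuals)
    enter as WLS weights.  Requires >= 2 distinct temperatures.  If the fitted
    slope is not positive the result is returned with ``t_b``/``dd`` undefined
    and a warning is emitted.
    """
    t, y, w = _to_arrays(obs)
    if np.unique(t).size < 2:
        raise FitError("linear fit needs >= 2 distinct temperatures")
    model = sm.WLS(y, sm.add_constant(t), weights=w)
    with warnings.catch_warnings():
        # saturated fits (n_obs == 2) have zero residual dof; SEs are then nan
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
        a, b = float(res.params[0]), float(res.params[1])
        se_a, se_b = float(res.bse[0]), float(res.bse[1])
    try:
        r2 = r_squared(y, a + b * t)
    except UndefinedResultError:
        r2 = math.nan  # flat observed rates: R² carries no information
    if b <= _B_TINY:
        warnings.warn(
            "fitted slope b <= 0: lower threshold and degree-day requirement undefined",
            stacklevel=2,
        )
    return LinearFitResult(a=a, b=b, se_a=se_a, se_b=se_b, r2=r2, n_obs=t.size)


def linear_lower_threshold(a: float, b: float) -> float:
    """Lower developmental threshold Tb = -a/b (°C) of the linear model."""
    if b == 0:
        raise UndefinedResultError("Tb undefined for zero slope")
    return -a / b


def linear_degree_days(b: float) -> float:
    """Degree-day requirement DD = 1/b of the linear model.

    Only a positive slope gives a meaningful thermal constant.
    """
    if b <= 0:
        raise UndefinedResultError("DD undefined for non-positive slope")
    return 1.0 / b


# ---------------------------------------------------------------------------
# Brière model

def briere_rate(temperature, n_coef: float, t_b: float, t_l: float, m: float):
    """Brière development rate n*T*(T-Tb)*(TL-T)^(1/m), clamped to 0 outside
    [Tb, TL] where development is theoretically not possible.

    Accepts scalar or array temperature; m > 0 and Tb < TL are required.
    """
    if not m > 0:
        raise ValueError("exponent m must be > 0")
    if not t_l > t_b:
        raise ValueError(f"upper threshold must exceed lower (got Tb={t_b}, TL={t_l})")
    t = np.asarray(temperature, dtype=float)
    inside = (t >= t_b) & (t <= t_l)
    rate = np.zeros_like(t)
    ts = t[inside]
    rate[inside] = n_coef * ts * (ts - t_b) * np.power(t_l - ts, 1.0 / m)
    if np.ndim(temperature) == 0:
        return float(rate)
    return rate


def briere_optimum(t_b: float, t_l: float, m: float) -> float:
    """Closed-form temperature maximizing the Brière curve on (Tb, TL).

    Setting d/dT [T(T-Tb)(TL-T)^(1/m)] = 0 gives the quadratic whose upper
    root is

        Topt = [2m*TL + (m+1)*Tb + sqrt(4m²TL² + (m+1)²Tb² - 4m²Tb*TL)]
               / (4m + 2)
    """
    if not m > 0:
        raise ValueError("exponent m must be > 0")
    if not t_l > t_b:
        raise ValueError(f"upper threshold must exceed lower (got Tb={t_b}, TL={t_l})")
    disc = 4 * m**2 * t_l**2 + (m + 1) ** 2 * t_b**2 - 4 * m**2 * t_b * t_l
    return (2 * m * t_l + (m + 1) * t_b + math.sqrt(disc)) / (4 * m + 2)


@dataclass(frozen=True)
class BriereBounds:
    """Box bounds for the Brière fit parameters.

    Defaults follow the biology: the lower threshold must lie below the
    coolest temperature at which development was observed, the upper threshold
    above the warmest observed temperature (45 °C ceiling), and the exponent
    within the range seen across published insect fits.
    """

    t_b: tuple[float, float] = (0.0, math.nan)  # nan -> min observed T
    t_l: tuple[float, float] = (math.nan, 45.0)  # nan -> max observed T
    m: tuple[float, float] = (0.3, 6.0)

    def resolve(self, t: np.ndarray) -> "BriereBounds":
        lo_b, hi_b = self.t_b
        lo_l, hi_l = self.t_l
        if math.isnan(hi_b):
            hi_b = float(t.min())
        if math.isnan(lo_l):
            lo_l = float(t.max())
        if not lo_b < hi_b or not lo_l < hi_l:
            raise FitError(f"empty Brière bounds: t_b={lo_b, hi_b}, t_l={lo_l, hi_l}")
        return BriereBounds(t_b=(lo_b, hi_b), t_l=(lo_l, hi_l), m=self.m)


@dataclass(frozen=True)
class BriereFitResult:
    """Least-squares Brière fit with derived optimum temperature.

    ``t_opt`` is the closed-form maximizer for the fitted (t_b, t_l, m);
    ``underdetermined`` flags fits with fewer distinct temperatures than free
    parameters (thresholds then lean on the bounds), ``at_bounds`` flags a
    solution on a box boundary.
    """

    n_coef: float
    t_b: float
    t_l: float
    m: float
    r2: float
    n_obs: int
    rss: float
    converged: bool
    n_starts: int
    at_bounds: bool = False
    underdetermined: bool = False
    se: dict | None = None

    @property
    def t_opt(self) -> float:
        return briere_optimum(self.t_b, self.t_l, self.m)

    def predict(self, temperature):
        return briere_rate(temperature, self.n_coef, self.t_b, self.t_l, self.m)


def _briere_basis(t: np.ndarray, t_b: float, t_l: float, m: float) -> np.ndarray:
    inside = (t >= t_b) & (t <= t_l)
    f = np.zeros_like(t)
    f[inside] = t[inside] * (t[inside] - t_b) * np.power(t_l - t[inside], 1.0 / m)
    return f


def fit_briere(
    obs: Iterable[RateObservation],
    bounds: BriereBounds | None = None,
    grid_shape: tuple[int, int, int] = (5, 5, 5),
) -> BriereFitResult:
    """Fit the Brière model by weighted least squares with multistart.

    Starts are a deterministic ``grid_shape`` grid of (Tb, TL, m) evenly
    spaced inside the bounds; at each start the scale coefficient n is set to
    its conditional closed-form optimum, then all four parameters are refined
    with a bounded trust-region solver.  The best objective wins; ties go to
    the earliest start in grid order.

    Requires >= 3 distinct temperatures and an effective sample size (sum of
    observation weights) >= 4; with only 3 distinct temperatures the
    four-parameter fit is flagged ``underdetermined`` (the thresholds are
    then constrained mostly by the bounds, as is unavoidable when development
    is observed at few temperatures).
    """
    t, y, w = _to_arrays(obs)
    n_distinct = np.unique(t).size
    if n_distinct < 3 or w.sum() < 4:
        raise FitError(
            f"Brière fit needs >= 3 distinct temperatures and effective n >= 4 "
            f"(got {n_distinct} distinct, effective n {w.sum():g})"
        )
    bounds = (bounds or BriereBounds()).resolve(t)
    sw = np.sqrt(w)

    def residuals(p: np.ndarray) -> np.ndarray:
        n_coef, t_b, t_l, m = p
        return sw * (y - briere_rate(t, n_coef, t_b, t_l, m))

    (b_lo, b_hi), (l_lo, l_hi), (m_lo, m_hi) = bounds.t_b, bounds.t_l, bounds.m
    # interior grid nodes: midpoints of an even partition, so no start sits on
    # a bound or at a degenerate t_b = min(T) / t_l = max(T) corner
    nb, nl, nm = grid_shape
    tb_grid = b_lo + (np.arange(nb) + 0.5) / nb * (b_hi - b_lo)
    tl_grid = l_lo + (np.arange(nl) + 0.5) / nl * (l_hi - l_lo)
    m_grid = m_lo + (np.arange(nm) + 0.5) / nm * (m_hi - m_lo)

    lower = np.array([0.0, b_lo, l_lo, m_lo])
    upper = np.array([np.inf, b_hi, l_hi, m_hi])
    # keep thresholds strictly bracketing the data for the solver
    eps = 1e-9
    lower[2] = max(lower[2], float(t.max()) + eps)
    upper[1] = min(upper[1], float(t.min()) - eps)
    if lower[1] >= upper[1] or lower[2] >= upper[2]:
        raise FitError("bounds incompatible with observed temperature range")

    best = None
    best_cost = np.inf
    n_starts = 0
    for t_b0 in tb_grid:
        t_b0 = min(max(t_b0, lower[1]), upper[1])
        for t_l0 in tl_grid:
            t_l0 = min(max(t_l0, lower[2]), upper[2])
            for m0 in m_grid:
                basis = _briere_basis(t, t_b0, t_l0, m0)
                denom = float(np.sum(w * basis**2))
                n0 = float(np.sum(w * basis * y)) / denom if denom > 0 else 1e-5
                n0 = max(n0, 1e-12)
                n_starts += 1
                try:
                    sol = least_squares(
                        residuals,
                        x0=np.array([n0, t_b0, t_l0, m0]),
                        bounds=(lower, upper),
                        method="trf",
                        xtol=1e-12,
                        ftol=1e-12,
                        gtol=1e-12,
                        max_nfev=400,
                    )
                except Exception:
                    continue
                if sol.cost < best_cost:
                    best, best_cost = sol, sol.cost
    if best is None:
        raise FitError("no Brière start converged; check data and bounds")

    n_coef, t_b, t_l, m = (float(v) for v in best.x)
    rss = float(np.sum((y - briere_rate(t, n_coef, t_b, t_l, m)) ** 2))
    try:
        r2 = r_squared(y, briere_rate(t, n_coef, t_b, t_l, m))
    except UndefinedResultError:
        r2 = math.nan
    at_bounds = bool(
        np.any(np.isclose(best.x[1:], lower[1:], atol=1e-6))
        or np.any(np.isclose(best.x[1:], upper[1:], atol=1e-6))
    )
    se = _briere_se(best, t.size)
    return BriereFitResult(
        n_coef=n_coef,
        t_b=t_b,
        t_l=t_l,
        m=m,
        r2=r2,
        n_obs=t.size,
        rss=rss,
        converged=bool(best.success),
        n_starts=n_starts,
        at_bounds=at_bounds,
        underdetermined=n_distinct < 4,
        se=se,
    )


def _briere_se(sol, n_obs: int) -> dict | None:
    """Approximate standard errors from the local quadratic model (J'J)."""
    dof = n_obs - sol.x.size
    if dof <= 0:
        return None
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (2 * sol.cost / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return None
    return {"n_coef": float(se[0]), "t_b": float(se[1]), "t_l": float(se[2]), "m": float(se[3])}
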