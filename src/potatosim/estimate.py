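"""Parameter estimation from field observation series.

Four estimators mirror how the crop parameters are obtained from trial
data: nonlinear least squares of the beta function against canopy-cover
observations, nonlinear least squares of the Gompertz curve against
harvest-index observations, radiation-use efficiency as the through-origin
slope of total dry biomass on cumulative intercepted PAR, and a quadratic
fit of early-season canopy cover to locate the day of 1% ground cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .growth import CanopyParameters, PartitionParameters, beta_canopy, gompertz_partition

__all__ = [
    "CanopySeries",
    "BiomassSeries",
    "FitResult",
    "RueEstimate",
    "fit_beta_canopy",
    "fit_gompertz_hi",
    "estimate_rue",
    "days_to_one_percent_cover",
]

# Solver settings: tight parameter tolerance, bounded iterations, and a
# small deterministic multi-start fallback when the data-driven start fails.
_XTOL = 1e-10
_MAX_ITER = 500
_N_MULTISTART = 5
_MULTISTART_SEED = 20130301


@dataclass(frozen=True)
class CanopySeries:
    """Canopy-cover observations (tt or day on the x-axis, cover fraction).

    Rows are sorted on construction so fits are order-invariant.
    """

    x: np.ndarray
    cover: np.ndarray

    def __init__(self, x, cover):
        x = np.asarray(x, dtype=float)
        cover = np.asarray(cover, dtype=float)
        if x.shape != cover.shape or x.ndim != 1:
            raise ValueError("x and cover must be 1-D arrays of equal length")
        order = np.argsort(x)
        x, cover = x[order], cover[order]
        if np.any(np.diff(x) <= 0):
            raise ValueError("x values must be distinct")
        if np.any((cover < 0) | (cover > 1)):
            raise ValueError("cover values must lie in [0, 1]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "cover", cover)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BiomassSeries:
    """Destructive-sampling series: total and tuber dry mass (g·m⁻²) per day."""

    day: np.ndarray
    total_dm: np.ndarray
    tuber_dm: np.ndarray

    def __init__(self, day, total_dm, tuber_dm):
        day = np.asarray(day, dtype=int)
        total_dm = np.asarray(total_dm, dtype=float)
        tuber_dm = np.asarray(tuber_dm, dtype=float)
        if not (day.shape == total_dm.shape == tuber_dm.shape):
            raise ValueError("day, total_dm, tuber_dm must have equal length")
        order = np.argsort(day)
        day, total_dm, tuber_dm = day[order], total_dm[order], tuber_dm[order]
        if np.any(np.diff(day) <= 0):
            raise ValueError("days must be distinct")
        if np.any(total_dm < 0) or np.any(tuber_dm < 0):
            raise ValueError("masses must be non-negative")
        if np.any(tuber_dm > total_dm * (1 + 1e-9)):
            raise ValueError("tuber dry mass cannot exceed total dry mass")
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "total_dm", total_dm)
        object.__setattr__(self, "tuber_dm", tuber_dm)

    def __len__(self) -> int:
        return len(self.day)

    @property
    def harvest_index(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_dm > 0, self.tuber_dm / self.total_dm, 0.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear fit: estimates plus honesty metadata."""

    params: object
    rss: float
    r_squared: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.rss < -1e-12:
            raise ValueError("negative residual sum of squares")


@dataclass(frozen=True)
class RueEstimate:
    """Radiation-use efficiency (g dry mass per MJ intercepted PAR)."""

    rue: float
    stderr: float
    r_squared: float
    n: int
    intercept: float = 0.0


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    if tss == 0:
        return 0.0
    return 1.0 - rss / tss


def _run_nls(residual_fn, x0, bounds, rng_scales):
    """least_squares with a deterministic jittered multi-start fallback."""
    best = None
    tries = [np.asarray(x0, dtype=float)]
    rng = np.random.default_rng(_MULTISTART_SEED)
    for _ in range(_N_MULTISTART):
        jitter = rng.uniform(0.7, 1.3, size=len(x0))
        tries.append(np.clip(np.asarray(x0) * jitter, bounds[0], bounds[1]))
    for i, start in enumerate(tries):
        try:
            res = least_squares(
                residual_fn, start, bounds=bounds, xtol=_XTOL,
                max_nfev=_MAX_ITER,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        # the data-driven start converging cleanly is the common case
        if i == 0 and res.status > 0 and res.cost < 1e-20:
            break
    return best


def fit_beta_canopy(
    series: CanopySeries, init: CanopyParameters | None = None
) -> FitResult:
    """Fit the beta canopy function to cover observations by least squares.

    The default initializer is data-driven: wmax from the maximum observed
    cover, te from the last observation, tm from the point of maximum
    finite-difference growth rate.  The fit is parameterized as
    (wmax, tm, te − tm) so the tm < te constraint holds by construction.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 observations to fit 3 parameters")
    x, y = series.x, series.cover
    if init is not None:
        x0 = [init.wmax, init.tm, init.te - init.tm]
    else:
        rates = np.diff(y) / np.diff(x)
        tm0 = float(x[:-1][np.argmax(rates)]) if np.any(rates > 0) else float(x[len(x) // 2])
        te0 = float(x[-1])
        x0 = [max(float(y.max()), 1e-3), max(tm0, 1e-3), max(te0 - tm0, 1.0)]
    lo = [1e-6, 0.0, 1e-3]
    hi = [1.0, np.inf, np.inf]

    def resid(p):
        wmax, tm, dte = p
        cp = CanopyParameters.__new__(CanopyParameters)
        object.__setattr__(cp, "wmax", wmax)
        object.__setattr__(cp, "tm", tm)
        object.__setattr__(cp, "te", tm + dte)
        return beta_canopy(x, cp) - y

    res = _run_nls(resid, x0, (lo, hi), None)
    if res is None:
        return FitResult(None, float(np.sum(y**2)), 0.0, False, _MAX_ITER)
    wmax, tm, dte = res.x
    params = CanopyParameters(min(max(wmax, 1e-9), 1.0), tm, tm + dte)
    return FitResult(
        params=params,
        rss=2 * float(res.cost),
        r_squared=_r_squared(y, res.fun),
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )


def fit_gompertz_hi(
    series: Sequence[tuple[float, float]] | CanopySeries,
    init: PartitionParameters | None = None,
) -> FitResult:
    """Fit the Gompertz harvest-index curve to (tt, HI) observations.

    a_max is constrained to (0, 1].  Degenerate inputs (all-zero or
    constant harvest indices) are flagged as non-converged rather than
    returning a spurious parameter set.
    """
    if isinstance(series, CanopySeries):
        x, y = series.x, series.cover
    else:
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("series must be (tt, hi) pairs")
        order = np.argsort(arr[:, 0])
        x, y = arr[order, 0], arr[order, 1]
    if len(x) < 4:
        raise ValueError("need at least 4 observations to fit 3 parameters")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("harvest-index values must lie in [0, 1]")
    if np.all(y <= 0) or np.ptp(y) < 1e-12:
        return FitResult(None, float(np.sum((y - y.mean()) ** 2)), 0.0, False, 0)

    if init is not None:
        x0 = [init.a_max, init.tu, init.b]
    else:
        increments = np.diff(y) / np.diff(x)
        tu0 = float(x[:-1][np.argmax(increments)]) if np.any(increments > 0) else float(np.median(x))
        x0 = [max(float(y.max()), 1e-3), max(tu0, 1.0), max((x[-1] - x[0]) / 5.0, 1.0)]
    lo = [1e-6, 1e-6, 1e-6]
    hi = [1.0, np.inf, np.inf]

    def resid(p):
        a, tu, b = p
        return a * np.exp(-np.exp(-(x - tu) / b)) - y

    res = _run_nls(resid, x0, (lo, hi), None)
    if res is None:
        return FitResult(None, float(np.sum(y**2)), 0.0, False, _MAX_ITER)
    a, tu, b = res.x
    params = PartitionParameters(min(max(a, 1e-9), 1.0), tu, b)
    return FitResult(
        params=params,
        rss=2 * float(res.cost),
        r_squared=_r_squared(y, res.fun),
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )


def estimate_rue(
    biomass: BiomassSeries,
    ipar_cumulative: pd.Series,
    through_origin: bool = True,
) -> RueEstimate:
    """Radiation-use efficiency from the biomass ~ cumulative-IPAR relation.

    Parameters
    ----------
    biomass : BiomassSeries
        Destructive-sampling observations of total dry biomass.
    ipar_cumulative : pandas.Series
        Cumulative intercepted PAR (MJ·m⁻²) indexed by day; every biomass
        sampling day must be present.
    through_origin : bool
        Regress through the origin (default) — zero interception implies
        zero biomass.  With ``False`` an intercept is included for
        diagnostics.
    """
    if len(biomass) < 2:
        raise ValueError("need at least 2 biomass observations")
    missing = [d for d in biomass.day if d not in ipar_cumulative.index]
    if missing:
        raise ValueError(f"biomass day(s) {missing} absent from IPAR series")
    x = ipar_cumulative.loc[biomass.day].to_numpy(dtype=float)
    y = biomass.total_dm
    if np.ptp(x) == 0:
        raise ValueError("IPAR has zero variance over sampling days")
    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if through_origin:
        slope, se, intercept = fit.params[0], fit.bse[0], 0.0
    else:
        intercept, slope = fit.params
        se = fit.bse[1]
    return RueEstimate(
        rue=float(slope),
        stderr=float(se),
        r_squared=float(fit.rsquared),
        n=len(biomass),
        intercept=float(intercept),
    )


def days_to_one_percent_cover(
    series: CanopySeries, threshold: float = 0.01
) -> float:
    """Day at which canopy cover first reaches 1%, from a quadratic fit.

    A quadratic ``cover(day)`` is fit to the early-season observations
    (up to the first maximum of cover) and the smallest real root of
    ``cover(day) = threshold`` within the observed span is returned.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 observations for a quadratic fit")
    x, y = series.x, series.cover
    # restrict to the rising phase: points up to the first maximum
    imax = int(np.argmax(y))
    x, y = x[: imax + 1], y[: imax + 1]
    if len(x) < 3:
        raise ValueError("fewer than 3 points before the cover maximum")
    if y.min() > threshold:
        raise ValueError("all observations above the threshold: no crossing in span")
    coeffs = np.polyfit(x, y, 2)
    coeffs[-1] -= threshold
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    if len(real) == 0:
        raise ValueError("quadratic has no real root: cannot locate the crossing")
    in_span = real[(real >= x[0] - 1e-9) & (real <= x[-1] + 1e-9)]
    if len(in_span) == 0:
        raise ValueError("no real root of the quadratic within the observed span")
    return float(in_span.min())
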