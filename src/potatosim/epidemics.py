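"""Late-blight epidemic analysis.

Disease pressure is summarized by the area under the disease progress
curve (AUDPC), the midpoint-rule integral of foliar severity over time:

    AUDPC = Σᵢ (yᵢ + yᵢ₊₁)/2 · (tᵢ₊₁ − tᵢ)       [%·days]

Yield losses are analysed by ordinary regression of yield on a disease
index, and tuberization dynamics by logistic curve fits whose midpoint
t50 marks the day of maximum tuberization rate.  Comparing fungicide-
controlled against uncontrolled plots gives the yield increase from
disease control and the shift in the maximum-rate day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "DiseaseAssessment",
    "YieldCurve",
    "LogisticFit",
    "RegressionResult",
    "audpc",
    "disease_index",
    "disease_yield_regression",
    "fit_logistic_curve",
    "yield_increase_percent",
    "max_rate_shift_days",
]


@dataclass(frozen=True)
class DiseaseAssessment:
    """Repeated foliar-severity readings (% leaf area affected) for one plot."""

    genotype: str
    treatment: str  # "controlled" | "uncontrolled"
    t: np.ndarray   # reading times (days; Julian or after planting)
    severity: np.ndarray  # % in [0, 100]

    def __init__(self, genotype, treatment, t, severity):
        t = np.asarray(t, dtype=float)
        severity = np.asarray(severity, dtype=float)
        if t.shape != severity.shape or t.ndim != 1:
            raise ValueError("t and severity must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("reading times must be strictly increasing")
        if np.any((severity < 0) | (severity > 100)):
            raise ValueError("severity must lie in [0, 100] %")
        object.__setattr__(self, "genotype", genotype)
        object.__setattr__(self, "treatment", treatment)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "severity", severity)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class YieldCurve:
    """Cumulative tuber yield sampled repeatedly through the season."""

    genotype: str
    treatment: str
    day: np.ndarray
    yield_: np.ndarray

    def __init__(self, genotype, treatment, day, yield_):
        day = np.asarray(day, dtype=float)
        yield_ = np.asarray(yield_, dtype=float)
        if day.shape != yield_.shape or day.ndim != 1:
            raise ValueError("day and yield must be 1-D arrays of equal length")
        if np.any(np.diff(day) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(yield_ < 0):
            raise ValueError("yields must be non-negative")
        object.__setattr__(self, "genotype", genotype)
        object.__setattr__(self, "treatment", treatment)
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "yield_", yield_)

    def __len__(self) -> int:
        return len(self.day)


@dataclass(frozen=True)
class LogisticFit:
    """Logistic curve K / (1 + exp(−r·(t − t50))); max rate at t50."""

    k: float
    r: float
    t50: float
    r_squared: float
    converged: bool

    @property
    def max_rate_day(self) -> float:
        return self.t50


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def audpc(assessment: DiseaseAssessment) -> float:
    """Area under the disease progress curve (%·days), midpoint rule."""
    if len(assessment) < 2:
        raise ValueError("AUDPC needs at least 2 readings")
    y, t = assessment.severity, assessment.t
    return float(np.sum((y[:-1] + y[1:]) / 2.0 * np.diff(t)))


def disease_index(assessment: DiseaseAssessment, normalized: bool = True) -> float:
    """Scalar disease index: AUDPC, optionally normalized to [0, 1].

    Normalization divides by (assessment span × 100), the AUDPC of a
    permanently fully-infected canopy, giving a unit-scaled predictor for
    regression against yield.
    """
    a = audpc(assessment)
    if not normalized:
        return a
    span = float(assessment.t[-1] - assessment.t[0])
    if span <= 0:
        raise ValueError("zero assessment span")
    return a / (span * 100.0)


def disease_yield_regression(pairs) -> RegressionResult:
    """OLS of yield on disease index across genotypes/plots.

    Late blight depresses yield, so the expected slope is negative; a
    positive fitted slope is reported but flagged with a warning.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (disease index, yield) tuples")
    if len(arr) < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("disease index has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    r2 = float(fit.rsquared) if np.ptp(y) > 0 else 0.0
    if slope > 1e-12:
        warnings.warn(
            "positive disease-yield slope: expected a negative association",
            stacklevel=2,
        )
    return RegressionResult(float(slope), float(intercept), r2, len(arr))


def fit_logistic_curve(curve: YieldCurve) -> LogisticFit:
    """Fit K / (1 + exp(−r·(t − t50))) to a cumulative yield curve.

    The rate r is constrained positive (yield accumulates); data without
    a rising sigmoid shape produce a poor fit that is flagged as
    non-converged (R² below 0.5) rather than raising.
    """
    if len(curve) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    t, y = curve.day, curve.yield_

    k0 = max(float(y.max()), 1e-6)
    half = 0.5 * k0
    t50_0 = float(t[np.argmin(np.abs(y - half))])
    r0 = 4.0 / max(float(t[-1] - t[0]), 1.0)

    def resid(p):
        k, r, t50 = p
        return k / (1.0 + np.exp(-r * (t - t50))) - y

    res = least_squares(
        resid,
        [k0, r0, t50_0],
        bounds=([1e-9, 1e-9, t[0] - 10 * (t[-1] - t[0])],
                [np.inf, np.inf, t[-1] + 10 * (t[-1] - t[0])]),
        xtol=1e-12,
        max_nfev=1000,
    )
    k, r, t50 = res.x
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(res.fun**2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    converged = bool(res.status > 0) and r2 >= 0.5
    return LogisticFit(float(k), float(r), float(t50), r2, converged)


def _final_yield(curve: YieldCurve) -> float:
    """Final yield: logistic asymptote when the fit converged, else last point."""
    try:
        fit = fit_logistic_curve(curve)
    except ValueError:
        fit = None
    if fit is not None and fit.converged:
        return fit.k
    return float(curve.yield_[-1])


def yield_increase_percent(
    controlled: YieldCurve, uncontrolled: YieldCurve
) -> float:
    """Percent yield increase from disease control.

    (final controlled − final uncontrolled) / final uncontrolled × 100.
    """
    fc = _final_yield(controlled)
    fu = _final_yield(uncontrolled)
    if fu <= 0:
        raise ValueError("uncontrolled final yield is zero: increase undefined")
    return (fc - fu) / fu * 100.0


def max_rate_shift_days(
    controlled: YieldCurve, uncontrolled: YieldCurve
) -> float:
    """Shift (days) of the maximum tuberization-rate day under control.

    Positive when disease control delays the logistic midpoint t50.
    """
    fc = fit_logistic_curve(controlled)
    fu = fit_logistic_curve(uncontrolled)
    if not fc.converged or not fu.converged:
        raise ValueError("logistic fit did not converge for one of the treatments")
    return fc.t50 - fu.t50
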