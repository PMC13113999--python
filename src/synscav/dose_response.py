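"""Linear dose-effect fitting and IC50 inverse prediction.

The scavenging rate y (%) is modelled as a straight line in
concentration x (ug/mL), y = a + b x, fitted by ordinary least squares.
The half-maximal scavenging concentration is the abscissa where the
fitted line crosses 50%:

    IC50 = (50 - a) / b.

Because IC50 is a ratio of correlated normal estimates, its confidence
interval is computed by Fieller's theorem (the inverse-prediction /
calibration interval), with a first-order delta-method interval offered
for comparison.  With g = t^2 s^2 / (b^2 Sxx), the Fieller limits at
level 1 - alpha are

    x_hat +/- correction, finite only when g < 1;

g >= 1 (slope not distinguishable from zero at that level) yields an
unbounded interval, reported as infinite limits with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

from .assay import DoseResponseSeries
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    NoPositiveCrossingError,
    ValidationError,
)

CIMethod = Literal["fieller", "delta"]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of scavenging (%) on concentration, with the sufficient
    statistics inverse prediction needs (Sxx, x-bar, residual SE)."""

    slope: float
    intercept: float
    n: int
    r_squared: float
    residual_se: float
    sxx: float
    x_mean: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class IC50Estimate:
    """Half-maximal scavenging concentration with its confidence interval."""

    value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    level: float = 0.95
    method: CIMethod = "fieller"
    extrapolated: bool = False
    unbounded: bool = False

    def round_sig(self, sig: int = 4) -> float:
        """Display rounding to ``sig`` significant figures."""
        if self.value == 0:
            return 0.0
        return round(self.value, sig - 1 - int(math.floor(math.log10(abs(self.value)))))


def fit_line(series: DoseResponseSeries) -> LinearFit:
    """Fit the dose-effect line for one series."""
    return fit_line_xy(series.x, series.y)


def fit_line_xy(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS of y on x with fit diagnostics.

    Raises on a degenerate design (all x equal); a flat response
    (slope 0) is a valid fit, it just yields no IC50.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 points to fit a line")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("all concentrations identical; cannot fit a line")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    # Constant y: the line y = const fits exactly; define R^2 = 1.
    r2 = 1.0 if tss == 0.0 else max(0.0, min(1.0, 1.0 - rss / tss))
    residual_se = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
    return LinearFit(
        slope=slope,
        intercept=intercept,
        n=n,
        r_squared=r2,
        residual_se=residual_se,
        sxx=sxx,
        x_mean=float(x.mean()),
    )


def ic50_from_fit(
    fit: LinearFit, x_range: tuple[float, float] | None = None
) -> IC50Estimate:
    """Point estimate of the 50%-crossing of the fitted line.

    ``extrapolated`` flags a crossing outside the tested concentration
    range (a warning, not an error).
    """
    if fit.slope <= 0:
        raise NoPositiveCrossingError(
            f"slope {fit.slope:.4g} <= 0: response does not increase through 50%"
        )
    value = (50.0 - fit.intercept) / fit.slope
    if value <= 0:
        raise NoPositiveCrossingError(
            f"fitted 50% crossing at {value:.4g} ug/mL is not positive"
        )
    extrapolated = bool(x_range and not (x_range[0] <= value <= x_range[1]))
    return IC50Estimate(value=value, extrapolated=extrapolated)


def ic50_confidence_interval(
    fit: LinearFit, level: float = 0.95, method: CIMethod = "fieller"
) -> tuple[float, float]:
    """Confidence interval for the 50%-crossing concentration.

    Fieller (default): exact under the linear-normal model; may be
    unbounded (infinite limits) when the slope is not significant at
    ``level``.  Delta: symmetric first-order interval, accurate when the
    slope t-statistic is large.
    """
    if fit.n < 3:
        raise InsufficientDataError("need >= 3 points for a residual-based interval")
    if fit.slope <= 0:
        raise NoPositiveCrossingError("confidence interval requires a positive slope")
    x0 = (50.0 - fit.intercept) / fit.slope
    s = fit.residual_se
    t = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    d = x0 - fit.x_mean
    if s == 0.0:
        return (x0, x0)
    if method == "fieller":
        g = (t * s) ** 2 / (fit.slope**2 * fit.sxx)
        if g >= 1.0:
            return (-math.inf, math.inf)
        half = (t * s / fit.slope) * math.sqrt(d**2 / fit.sxx + (1.0 - g) / fit.n)
        center = fit.x_mean + d / (1.0 - g)
        return (center - half / (1.0 - g), center + half / (1.0 - g))
    if method == "delta":
        se = (s / fit.slope) * math.sqrt(1.0 / fit.n + d**2 / fit.sxx)
        return (x0 - t * se, x0 + t * se)
    raise ValidationError(f"unknown CI method {method!r}")


def estimate_ic50(
    fit: LinearFit,
    x_range: tuple[float, float] | None = None,
    level: float = 0.95,
    method: CIMethod = "fieller",
) -> IC50Estimate:
    """Point estimate plus confidence interval in one record."""
    est = ic50_from_fit(fit, x_range)
    lo, hi = ic50_confidence_interval(fit, level=level, method=method)
    return replace(
        est,
        ci_low=lo,
        ci_high=hi,
        level=level,
        method=method,
        unbounded=not (math.isfinite(lo) and math.isfinite(hi)),
    )
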