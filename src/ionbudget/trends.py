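"""Polynomial trends, fluctuation thresholds and window detection.

Long ecological series are visualized and interpreted with low-order
polynomial trend lines fitted by ordinary least squares on a centered,
unit-scaled year axis. Three derived diagnostics matter here:

* the mean absolute residual (MAE) of a fit, rounded to a round number,
  serves as a "natural fluctuation zone" around the trend line;
* the maximal contiguous run of years whose fitted value falls below the
  negative threshold is the remobilization window (with crossing years
  refined by linear interpolation and rounded to integer years);
* an endpoint change smaller than the 90th percentile of the inter-annual
  fluctuations is declared uninterpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats

__all__ = [
    "TrendFit",
    "RemobilizationWindow",
    "LinearTrend",
    "fit_polynomial",
    "fluctuation_threshold",
    "detect_remobilization_window",
    "endpoint_change_interpretable",
    "linear_trend",
    "correlation_r2",
]


@dataclass(frozen=True)
class TrendFit:
    """An OLS polynomial fit of an annual series.

    ``poly`` maps raw years through a centered/scaled domain, so the fit is
    invariant to translating all years by a constant. ``fitted + residuals``
    reproduces the observations exactly by construction.
    """

    years: np.ndarray
    observed: np.ndarray
    degree: int
    poly: Polynomial
    fitted: np.ndarray
    residuals: np.ndarray
    mae: float

    def predict(self, years) -> np.ndarray:
        return self.poly(np.asarray(years, dtype=float))


def fit_polynomial(years: Sequence[float], values: Sequence[float], degree: int) -> TrendFit:
    """Least-squares polynomial of ``degree`` on a centered, scaled year axis."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape or years.ndim != 1:
        raise ValueError("years and values must be 1-D and equally long")
    if degree < 0 or degree >= len(years):
        raise ValueError(f"degree {degree} needs more than {degree} observations "
                         f"(got {len(years)})")
    poly = Polynomial.fit(years, values, deg=degree)
    fitted = poly(years)
    residuals = values - fitted
    return TrendFit(
        years=years, observed=values, degree=degree, poly=poly,
        fitted=fitted, residuals=residuals,
        mae=float(np.mean(np.abs(residuals))),
    )


def fluctuation_threshold(fit_or_mae: TrendFit | float, rounding: str = "nearest10") -> float:
    """Natural-fluctuation threshold derived from a fit's MAE.

    ``rounding="nearest10"`` (default) rounds to the nearest multiple of 10
    with ties toward zero (an MAE of 52.8 gives ±50); ``"none"`` returns the
    MAE unrounded.
    """
    mae = fit_or_mae.mae if isinstance(fit_or_mae, TrendFit) else float(fit_or_mae)
    if mae < 0:
        raise ValueError("MAE must be >= 0")
    if rounding == "none":
        return mae
    if rounding != "nearest10":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    tenths = mae / 10.0
    lower = math.floor(tenths)
    # nearest multiple of 10, ties toward zero
    return 10.0 * (lower if tenths - lower <= 0.5 else lower + 1)


@dataclass(frozen=True)
class RemobilizationWindow:
    """Contiguous span of years with fitted delta below the loss threshold."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year


def detect_remobilization_window(
    fit: TrendFit, threshold: float
) -> RemobilizationWindow | None:
    """The maximal run of years whose fitted value is below ``−threshold``.

    Crossing years at the window edges are located by linear interpolation
    between the adjacent grid years and rounded to the nearest integer year
    (a trend crossing −50 at 1988.2 starts the window in 1988). Returns
    ``None`` when no fitted value qualifies.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    years = fit.years
    f = fit.fitted
    below = f < -threshold
    if not below.any():
        return None

    # maximal contiguous run (first one on ties)
    best = (0, None, None)
    i = 0
    n = len(years)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 > best[0]:
                best = (j - i + 1, i, j)
            i = j + 1
        else:
            i += 1
    _, i0, j0 = best

    if i0 == 0:
        start = years[0]
    else:
        # f[i0-1] >= -threshold > f[i0]: linear crossing between grid years
        frac = (f[i0 - 1] + threshold) / (f[i0 - 1] - f[i0])
        start = years[i0 - 1] + frac * (years[i0] - years[i0 - 1])
    if j0 == n - 1:
        end = years[-1]
    else:
        frac = (f[j0] + threshold) / (f[j0] - f[j0 + 1])
        end = years[j0] + frac * (years[j0 + 1] - years[j0])

    return RemobilizationWindow(
        start_year=int(math.floor(start + 0.5)),
        end_year=int(math.floor(end + 0.5)),
    )


def endpoint_change_interpretable(
    fit: TrendFit,
    percentile: float = 90.0,
    method: str = "first_differences",
) -> tuple[bool, dict]:
    """Is the fitted endpoint-to-endpoint change larger than the noise?

    Compares ``|fitted(last) − fitted(first)|`` against the chosen
    percentile of the inter-annual fluctuations of the observed series —
    by default the absolute year-to-year first differences
    (``method="residuals"`` uses absolute fit residuals instead). A change
    below that percentile is not an interpretable trend. Scale-equivariant:
    multiplying the series by c > 0 does not change the verdict.
    """
    if len(fit.years) < 3:
        raise ValueError("need at least 3 years")
    change = abs(float(fit.fitted[-1] - fit.fitted[0]))
    if method == "first_differences":
        fluct = np.abs(np.diff(fit.observed))
    elif method == "residuals":
        fluct = np.abs(fit.residuals)
    else:
        raise ValueError(f"unknown method {method!r}")
    cutoff = float(np.percentile(fluct, percentile))
    return change >= cutoff, {
        "endpoint_change": change,
        "fluctuation_percentile": cutoff,
        "percentile": percentile,
        "method": method,
    }


@dataclass(frozen=True)
class LinearTrend:
    slope_per_year: float
    intercept: float
    p_value: float
    fitted_start: float
    fitted_end: float


def linear_trend(years: Sequence[float], values: Sequence[float]) -> LinearTrend:
    """OLS straight line with a two-sided t-test on the slope."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(years) == 0:
        raise ValueError("degenerate x: all years equal")
    res = stats.linregress(years, values)
    return LinearTrend(
        slope_per_year=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        fitted_start=float(res.intercept + res.slope * years[0]),
        fitted_end=float(res.intercept + res.slope * years[-1]),
    )


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of two equally long series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equally long series with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input series")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
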