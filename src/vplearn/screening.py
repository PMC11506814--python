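"""Pre-analysis screening: double-MAD outlier detection and descriptive
condition summaries.

Threshold distributions from adaptive procedures are typically right-skewed,
so a single MAD over- or under-flags one tail. The double MAD uses separate
scale estimates below and above the median: left MAD = median |x - m| over
x <= m, right MAD over x >= m. A value is an outlier when its absolute
deviation from the median exceeds ``threshold_multiplier`` times the MAD on
its own side. Flagged values are reported, not removed.
"""
from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy import stats

__all__ = ["ScreeningReport", "double_mad_outliers", "summarize_condition",
           "skewness_se"]


@dataclass(frozen=True)
class ScreeningReport:
    flags: np.ndarray
    left_mad: float
    right_mad: float
    threshold_multiplier: float

    @property
    def outlier_values(self) -> np.ndarray:
        return self._values[self.flags]

    def __post_init__(self):
        object.__setattr__(self, "_values", None)


def double_mad_outliers(values, threshold_multiplier: float = 3.0) -> ScreeningReport:
    """Flag outliers with side-specific MAD scales. A degenerate side MAD of
    zero means any nonzero deviation on that side is flagged."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError(f"need at least 3 values, got {np.atleast_1d(x).size}")
    if threshold_multiplier <= 0:
        raise ValueError(f"threshold_multiplier must be > 0, got {threshold_multiplier}")
    m = float(np.median(x))
    dev = np.abs(x - m)
    left_mad = float(np.median(dev[x <= m]))
    right_mad = float(np.median(dev[x >= m]))

    side_mad = np.where(x <= m, left_mad, right_mad)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(side_mad > 0, dev / np.where(side_mad > 0, side_mad, 1.0), np.inf)
    flags = (ratio > threshold_multiplier) & (dev > 0)

    report = ScreeningReport(
        flags=flags,
        left_mad=left_mad,
        right_mad=right_mad,
        threshold_multiplier=threshold_multiplier,
    )
    object.__setattr__(report, "_values", x)
    return report


def summarize_condition(values) -> tuple[float, float, float]:
    """(mean, SEM, skewness) of one condition's values. Skewness is the
    adjusted Fisher-Pearson coefficient (small-sample corrected); it is NaN
    for n < 3 or constant data."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"need at least 2 values, got {np.atleast_1d(x).size}")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(len(x)))
    skew = float(stats.skew(x, bias=False)) if len(x) >= 3 else float("nan")
    return mean, sem, skew


def skewness_se(n: int) -> float:
    """Standard error of the sample skewness, sqrt(6n(n-1)/((n-2)(n+1)(n+3)))."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
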