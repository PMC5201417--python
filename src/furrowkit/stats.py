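"""Nonparametric group comparisons and box-plot-style summaries.

Group differences are tested with the two-sided Mann-Whitney U test
(rank-sum): exact for small samples without ties, normal approximation
with tie correction otherwise.  Distribution summaries follow box-plot
conventions: median, quartiles, whiskers at the most extreme points
within 1.5 interquartile ranges of the box, outliers listed individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

__all__ = ["ComparisonResult", "BoxSummary", "mann_whitney", "box_summary"]

#: largest per-group n for which the exact null distribution is used
EXACT_N_MAX = 8


@dataclass
class ComparisonResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_a: float  # U statistic of group a
    u_b: float
    p_value: float
    method: str
    median_a: float
    median_b: float
    quartiles_a: tuple[float, float]
    quartiles_b: tuple[float, float]


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate((a, b))
    return np.unique(pooled).size < pooled.size


def mann_whitney(a, b, label_a: str = "a", label_b: str = "b"
                 ) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two samples.

    The exact null distribution is used when both groups have at most
    8 observations and there are no ties; otherwise the tie-corrected
    normal approximation (with continuity correction).  The identity
    U_a + U_b = n_a * n_b always holds.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX \
        and not _has_ties(a, b)
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    return ComparisonResult(
        label_a=label_a, label_b=label_b,
        n_a=int(a.size), n_b=int(b.size),
        u_a=u_a, u_b=float(a.size * b.size) - u_a,
        p_value=float(min(res.pvalue, 1.0)), method=method,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        quartiles_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        quartiles_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
    )


@dataclass
class BoxSummary:
    """Box-plot statistics with the 1.5*IQR outlier rule."""

    n: int
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: list[float] = field(default_factory=list)


def box_summary(values) -> BoxSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, q75 = np.percentile(v, [25, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(
        n=int(v.size), median=float(np.median(v)),
        q25=float(q25), q75=float(q75),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        outliers=sorted(float(x) for x in outliers))
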