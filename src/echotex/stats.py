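"""Correlation and group-comparison statistics for graded cohorts.

Implements the analysis conventions used throughout the pipeline:
Min-Max normalisation before correlation (a no-op for Pearson r, kept
for comparability of plotted scales), two-sided Pearson tests with a
four-band strength classification, the closed-form pooled-moment
Pearson coefficient between a grouping variable and a measurement, and
a normality-gated omnibus comparison (ANOVA or Kruskal–Wallis) with
rank-sum post hoc tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "min_max_normalize",
    "pearson_with_p",
    "classify_strength",
    "pooled_pearson_from_group_stats",
    "grade_comparison",
]

Strength = Literal["very strong", "moderately strong", "moderate", "weak"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    strength: Strength


def min_max_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale to [0, 1] by (x - min)/(max - min); constant input maps to 0."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 1:
        raise ValidationError("min_max_normalize requires at least one value")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def classify_strength(r: float) -> Strength:
    """Four-band strength label on |r|: >=0.80 very strong, [0.60, 0.80)
    moderately strong, [0.30, 0.60) moderate, <0.30 weak."""
    a = abs(r)
    if a > 1 + 1e-12:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    if a >= 0.80:
        return "very strong"
    if a >= 0.60:
        return "moderately strong"
    if a >= 0.30:
        return "moderate"
    return "weak"


def pearson_with_p(
    x: Sequence[float], y: Sequence[float], name: str = "column"
) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError(f"constant input in {name}: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r, p_value=float(res.pvalue), n=x.size, strength=classify_strength(r)
    )


def pooled_pearson_from_group_stats(
    ns: Sequence[int],
    means: Sequence[float],
    sds: Sequence[float],
    group_values: Sequence[float],
) -> float:
    """Exact Pearson r of (group value, measurement) pairs reconstructed
    from per-group sizes, means and SDs.

    Uses divisor-n (population) moments: the total measurement variance
    decomposes into the within-group part  sum(n_k * s_k^2)/N  and the
    between-group part  sum(n_k * (m_k - m)^2)/N, while the covariance
    with the group value g_k depends only on the group means.  Any
    dataset whose per-group moments match the inputs has exactly this
    correlation.
    """
    ns = np.asarray(ns, dtype=np.float64)
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    g = np.asarray(group_values, dtype=np.float64)
    if not (ns.shape == means.shape == sds.shape == g.shape):
        raise ValidationError("ns, means, sds, group_values must have equal length")
    if np.any(ns <= 0):
        raise ValidationError("group sizes must be positive")
    n_total = ns.sum()
    w = ns / n_total
    mu_y = w @ means
    mu_g = w @ g
    var_y = w @ (sds**2 + (means - mu_y) ** 2)
    var_g = w @ (g - mu_g) ** 2
    cov = w @ ((g - mu_g) * (means - mu_y))
    if var_y <= 0 or var_g <= 0:
        raise ValidationError("zero total variance: correlation undefined")
    return float(cov / np.sqrt(var_g * var_y))


@dataclass(frozen=True)
class GroupDescriptives:
    group: float
    n: int
    mean: float
    sd: float  # divisor n-1, as reported in descriptive tables


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[float, float]
    p_raw: float
    p_adjusted: float  # Bonferroni: min(1, m * p_raw)
    significant: bool


@dataclass(frozen=True)
class GroupComparisonResult:
    groups: tuple[GroupDescriptives, ...]
    omnibus_method: Literal["kruskal_wallis", "anova"]
    statistic: float
    p_value: float
    pairwise: tuple[PairwiseComparison, ...]


def grade_comparison(
    values: Sequence[float],
    grades: Sequence[int],
    method: Literal["auto", "kruskal", "anova"] = "auto",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Compare a measurement across grade groups.

    ``auto`` picks Kruskal–Wallis when any group fails a Shapiro–Wilk
    normality check at ``alpha``, ANOVA otherwise.  Post hoc: two-sided
    rank-sum (Mann–Whitney) tests for every pair, Bonferroni-corrected
    with m = number of pairs.
    """
    values = np.asarray(values, dtype=np.float64)
    grades = np.asarray(grades)
    if values.shape != grades.shape:
        raise ValidationError("values and grades must have equal length")
    levels = np.unique(grades)
    if levels.size < 2:
        raise ValidationError("need at least two groups")
    samples = {g: values[grades == g] for g in levels}
    for g, s in samples.items():
        if s.size < 2:
            raise ValidationError(f"group {g} has fewer than 2 values")

    descr = tuple(
        GroupDescriptives(
            group=float(g), n=int(s.size), mean=float(s.mean()),
            sd=float(s.std(ddof=1)),
        )
        for g, s in samples.items()
    )

    if method == "auto":
        normal = all(
            s.size >= 3 and np.ptp(s) > 0 and sps.shapiro(s).pvalue >= alpha
            for s in samples.values()
        )
        method = "anova" if normal else "kruskal"
    if method == "kruskal":
        stat, p = sps.kruskal(*samples.values())
        omnibus = "kruskal_wallis"
    else:
        stat, p = sps.f_oneway(*samples.values())
        omnibus = "anova"

    pairs = list(combinations(levels, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        p_raw = float(
            sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue
        )
        p_adj = min(1.0, m * p_raw)
        pairwise.append(
            PairwiseComparison(
                pair=(float(a), float(b)), p_raw=p_raw, p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )

    return GroupComparisonResult(
        groups=descr,
        omnibus_method=omnibus,
        statistic=float(stat),
        p_value=float(p),
        pairwise=tuple(pairwise),
    )
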