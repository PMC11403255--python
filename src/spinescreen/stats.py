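"""Nonparametric rank tests, summary statistics and behavioral scores.

The toolkit mirrors the analysis conventions of a typical behavioral /
morphometry study: two-sided Mann-Whitney U tests (exact by enumeration for
small tie-free samples, normal approximation with tie and continuity
corrections otherwise), Kruskal-Wallis with Dunn's post hoc z tests under a
Bonferroni-style family-wise adjustment, mean +/- SEM summaries, empirical
cumulative distributions, and the sociability index of the three-chamber
social interaction test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "RankTestResult",
    "PairwiseComparison",
    "SociabilityScore",
    "ECDF",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunns_posthoc",
    "sociability_index",
    "normalized_cdf",
    "mean_sem",
]

EXACT_MWU_MAX_N = 16  # exact enumeration threshold (total sample size)


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank test: statistic (U or H), p-value and metadata."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    tie_corrected: bool


@dataclass(frozen=True)
class PairwiseComparison:
    """One Dunn post hoc comparison."""

    group_a: str
    group_b: str
    z: float
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class SociabilityScore:
    """Sociability index with the interaction times it was computed from."""

    index: float
    time_novel_mouse_s: float
    time_novel_object_s: float


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} must contain at least one observation")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is the smaller of the two U statistics (computed
    from midranks).  The p-value is exact (full enumeration of rank splits)
    when the combined sample size is at most 16 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (pooled.size <= EXACT_MWU_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return RankTestResult(
        statistic=u,
        p_value=float(res.pvalue),
        method="mann-whitney-u/" + ("exact" if use_exact else "normal-approx"),
        n_per_group=(x.size, y.size),
        tie_corrected=has_ties and not use_exact,
    )


def kruskal_wallis(groups: Sequence) -> RankTestResult:
    """Kruskal-Wallis H test across two or more groups.

    H is tie-corrected; p comes from the chi-square distribution with k-1
    degrees of freedom.  A dataset in which every observation is identical
    carries no evidence against the null, so it returns H = 0, p = 1 (the
    tie-correction denominator would otherwise vanish).
    """
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2:
        raise ValidationError("kruskal_wallis requires at least two groups")
    pooled = np.concatenate(samples)
    if pooled.size < 3:
        raise ValidationError("kruskal_wallis requires at least three observations")
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    return RankTestResult(
        statistic=float(h),
        p_value=float(p),
        method="kruskal-wallis",
        n_per_group=tuple(s.size for s in samples),
        tie_corrected=has_ties,
    )


def dunns_posthoc(
    groups: Sequence,
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Dunn's post hoc pairwise z tests from pooled midranks.

    For groups i, j with mean pooled ranks R_i, R_j and sizes n_i, n_j,

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum over tie groups of (t^3 - t).  Unadjusted p-values are
    two-sided normal; the family-wise adjustment over all pairs is Bonferroni
    by default (matching common statistics-package conventions), with
    ``adjust`` in {"bonferroni", "holm", "none"}.  Adjusted p is capped at 1.
    """
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2:
        raise ValidationError("dunns_posthoc requires at least two groups")
    if adjust not in {"bonferroni", "holm", "none"}:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(samples))]
    if len(labels) != len(samples):
        raise ValidationError("labels must match the number of groups")

    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        start += s.size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n_total > 1:
        variance_factor = n_total * (n_total + 1) / 12.0 - tie_term / (
            12.0 * (n_total - 1)
        )
    else:  # pragma: no cover - guarded by sample validation
        variance_factor = 0.0

    zs, ps, pairs = [], [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se_sq = variance_factor * (1.0 / samples[i].size + 1.0 / samples[j].size)
            if se_sq <= 0:  # every observation tied: no evidence either way
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se_sq)
            zs.append(z)
            ps.append(2.0 * sps.norm.sf(abs(z)))
            pairs.append((labels[i], labels[j]))

    if adjust == "none":
        adjusted = list(ps)
    else:
        adjusted = list(multipletests(ps, method=adjust)[1])
    return [
        PairwiseComparison(a, b, z, p, min(1.0, p_adj))
        for (a, b), z, p, p_adj in zip(pairs, zs, ps, adjusted)
    ]


def sociability_index(
    time_novel_mouse_s: float, time_novel_object_s: float
) -> SociabilityScore:
    """Sociability index: time with the novel mouse over time with novel
    mouse plus novel object.  0.5 means no preference; centre-chamber time is
    excluded by definition.
    """
    t_m, t_o = float(time_novel_mouse_s), float(time_novel_object_s)
    if t_m < 0 or t_o < 0:
        raise ValidationError("interaction times must be non-negative")
    if t_m + t_o == 0:
        raise ValidationError(
            "sociability index undefined: both interaction times are zero"
        )
    return SociabilityScore(t_m / (t_m + t_o), t_m, t_o)


class ECDF:
    """Right-continuous empirical cumulative distribution function.

    ``ecdf(v)`` is the fraction of observations at or below ``v``; it steps
    from 0 to exactly 1 over the sorted sample values.
    """

    def __init__(self, sample) -> None:
        arr = _as_sample(sample, "sample")
        self.sorted_values = np.sort(arr)
        self.n = arr.size
        self.x, counts = np.unique(self.sorted_values, return_counts=True)
        self.y = np.cumsum(counts) / self.n

    def __call__(self, v) -> np.ndarray | float:
        v_arr = np.asarray(v, dtype=float)
        out = np.searchsorted(self.sorted_values, v_arr, side="right") / self.n
        return float(out) if np.isscalar(v) or v_arr.ndim == 0 else out


def normalized_cdf(sample) -> ECDF:
    """Normalized cumulative distribution (ECDF) of a sample."""
    return ECDF(sample)


def mean_sem(sample) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD with n-1 denominator
    over sqrt(n)).  Requires at least two observations."""
    arr = _as_sample(sample, "sample")
    if arr.size < 2:
        raise ValidationError("SEM undefined for fewer than two observations")
    return float(arr.mean()), float(sps.sem(arr, ddof=1))
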