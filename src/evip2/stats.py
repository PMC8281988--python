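"""Nonparametric statistical primitives used throughout the pipeline.

The decision tree rests on four primitives: Spearman rank correlation,
the Kruskal-Wallis H test, the two-sided unpaired rank-sum
(Wilcoxon/Mann-Whitney) test, and Benjamini-Hochberg step-up adjustment.
They are implemented here from the rank definitions; only the chi-square
and normal distribution functions come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

__all__ = [
    "TestResult",
    "average_ranks",
    "spearman_rho",
    "kruskal_wallis",
    "ranksum_two_sided",
    "benjamini_hochberg",
    "bonferroni",
]

# exact rank-sum enumeration stays cheap up to C(12, 6) = 924 subsets
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: statistic, p-value and the group sizes."""

    statistic: float
    pvalue: float
    n_per_group: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their positions."""
    x = np.asarray(x, dtype=float)
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    i = 0
    sx = x[order]
    while i < n:
        j = i
        while j + 1 < n and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of average ranks.

    Requires vectors of equal length >= 3; a constant vector has no rank
    ordering and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = average_ranks(x) - (x.size + 1) / 2.0
    ry = average_ranks(y) - (y.size + 1) / 2.0
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    rho = float(rx @ ry) / denom
    return float(min(1.0, max(-1.0, rho)))


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    H is computed from mean ranks of the pooled sample and referred to a
    chi-square distribution with k - 1 degrees of freedom. All values
    identical yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    sizes = tuple(int(g.size) for g in groups)
    n_total = sum(sizes)
    if n_total < 5:
        raise ValueError("need a total of at least 5 observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, pvalue=1.0, n_per_group=sizes)
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        r_mean = float(ranks[start : start + size].mean())
        h += size * (r_mean - (n_total + 1) / 2.0) ** 2
        start += size
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    h /= correction
    p = float(_chi2.sf(h, df=len(groups) - 1))
    return TestResult(statistic=float(h), pvalue=min(1.0, p), n_per_group=sizes)


def _exact_ranksum_pvalue(n_a: int, n_b: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum of group a (no ties assumed)."""
    n = n_a + n_b
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for combo in combinations(range(1, n + 1), n_a):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def ranksum_two_sided(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided unpaired rank-sum (Wilcoxon/Mann-Whitney) test.

    Exact enumeration of the rank-sum null distribution when the pooled
    size is small and there are no ties; otherwise a normal approximation
    with tie and continuity corrections. The statistic reported is the
    rank sum of ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    n_a, n_b = int(a.size), int(b.size)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = average_ranks(pooled)
    w = float(ranks[:n_a].sum())
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_RANKSUM_MAX_N and not has_ties:
        p = _exact_ranksum_pvalue(n_a, n_b, w)
        return TestResult(statistic=w, pvalue=min(1.0, p), n_per_group=(n_a, n_b))
    mu = n_a * (n + 1) / 2.0
    tie = _tie_term(pooled)
    var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:  # every value tied: the null is exactly true
        return TestResult(statistic=w, pvalue=1.0, n_per_group=(n_a, n_b))
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * float(_norm.sf(max(z, 0.0)))
    return TestResult(statistic=w, pvalue=min(1.0, p), n_per_group=(n_a, n_b))


def _validated_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d sequence")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = _validated_pvals(pvals)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bonferroni(pvals) -> np.ndarray:
    """Bonferroni-adjusted p-values, clipped to 1."""
    p = _validated_pvals(pvals)
    return np.minimum(p * p.size, 1.0) if p.size else p.copy()
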