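"""Nonparametric population statistics, implemented from first principles.

Each test carries an exact small-sample branch (full enumeration of the
permutation/sign null, computed by dynamic programming over rank sums) and
a tie-corrected large-sample approximation. Two-sided p-values follow the
doubled-smaller-tail convention (capped at 1), matching R's conventions
for these tests.

Covered: Wilcoxon signed-rank (paired), Mann-Whitney rank-sum, McNemar's
paired-proportions test, the Friedman test with a permutation option, the
Pearson chi-square homogeneity-of-proportions test, and the Marascuillo
procedure for pairwise multiple comparisons of proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ProportionTable",
    "wilcoxon_signed_rank",
    "rank_sum",
    "mcnemar",
    "friedman",
    "chisq_homogeneity",
    "two_proportions_chisq",
    "marascuillo",
    "bonferroni",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    method: str = ""


@dataclass(frozen=True)
class ProportionTable:
    """Groups of (label, successes, n) for proportion comparisons."""

    groups: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for label, s, n in self.groups:
            if n <= 0:
                raise ValueError(f"group {label}: n must be positive")
            if not 0 <= s <= n:
                raise ValueError(f"group {label}: successes outside [0, n]")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([s / n for _, s, n in self.groups])


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their midrank."""
    return sps.rankdata(values, method="average")


def _two_sided_from_tail(lo_tail: float, hi_tail: float) -> float:
    return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))


def _rank_sum_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of subset-sum values over all 2^n sign assignments.

    ``doubled_ranks`` are 2x the midranks (integers even with .5 ties).
    Returns an array c where c[s] = number of sign patterns whose positive
    doubled-rank sum equals s.
    """
    total = int(round(doubled_ranks.sum()))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for d in doubled_ranks:
        d = int(round(d))
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: counts.size - d]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded; tied absolute differences receive
    midranks. Exact enumeration of the 2^n sign null (via DP over rank
    sums) for n <= ``exact_max_n``; otherwise a tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, method="degenerate: all differences zero")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        counts = _rank_sum_counts(doubled)
        total = counts.sum()
        w2 = int(round(2 * w_pos))
        lo = counts[: w2 + 1].sum() / total
        hi = counts[w2:].sum() / total
        return TestResult(w_pos, _two_sided_from_tail(lo, hi), method="exact")
    # tie-corrected variance; ties enter via the midrank sum of squares
    sigma2 = float(np.sum(ranks**2)) / 4.0
    if sigma2 == 0:
        return TestResult(w_pos, 1.0, method="degenerate")
    z = (abs(w_pos - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return TestResult(w_pos, float(2 * sps.norm.sf(z)), method="normal")


def rank_sum(x, y, exact_max_n: int = 20) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact null distribution (DP over which midranks fall in the first
    sample) for m + n <= ``exact_max_n``; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_x = float(ranks[:m].sum())
    if m + n <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        total_sum = int(doubled.sum())
        # dp[c, s] = number of c-subsets of midranks with doubled sum s
        dp = np.zeros((m + 1, total_sum + 1))
        dp[0, 0] = 1.0
        for d in doubled:
            for c in range(m - 1, -1, -1):
                row = dp[c]
                tgt = dp[c + 1]
                tgt[d:] += row[: total_sum + 1 - d]
        dist = dp[m]
        total = dist.sum()
        w2 = int(round(2 * w_x))
        lo = dist[: w2 + 1].sum() / total
        hi = dist[w2:].sum() / total
        return TestResult(w_x, _two_sided_from_tail(lo, hi), method="exact")
    mu = m * (m + n + 1) / 2.0
    # tie correction for the rank-sum variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    N = m + n
    sigma2 = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return TestResult(w_x, 1.0, method="degenerate")
    z = max((abs(w_x - mu) - 0.5) / np.sqrt(sigma2), 0.0)
    return TestResult(w_x, float(2 * sps.norm.sf(z)), method="normal")


def mcnemar(b: int, c: int, exact_max_n: int = 25) -> TestResult:
    """McNemar's test on the two discordant-pair counts.

    Exact two-sided binomial(b+c, 1/2) for b + c < ``exact_max_n``;
    continuity-corrected chi-square otherwise. b + c = 0 gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    nd = b + c
    if nd == 0:
        return TestResult(0.0, 1.0, method="degenerate: no discordant pairs")
    if nd < exact_max_n:
        lo = float(sps.binom.cdf(b, nd, 0.5))
        hi = float(sps.binom.sf(b - 1, nd, 0.5))
        return TestResult(float(b), _two_sided_from_tail(lo, hi), method="exact")
    stat = (abs(b - c) - 1.0) ** 2 / nd
    return TestResult(stat, float(sps.chi2.sf(stat, 1)), df=1, method="chi2-corrected")


def _friedman_q(rank_matrix: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from a blocks x conditions midrank matrix."""
    n, k = rank_matrix.shape
    col_sums = rank_matrix.sum(axis=0)
    a = float(np.sum(rank_matrix**2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every block constant
        return 0.0
    return (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / (a - c)


def friedman(matrix, exact: bool | None = None, exact_max_cells: int = 200_000) -> TestResult:
    """Friedman test on a blocks x conditions matrix (midranks within block).

    p from the chi-square(k-1) reference by default; when ``exact`` is True
    (or None with few enough blocks) the permutation null — all within-block
    orderings, enumerated exhaustively — is used instead.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x conditions)")
    n, k = m.shape
    if k < 3 or n < 2:
        raise ValueError("need >= 3 conditions and >= 2 blocks")
    ranks = np.vstack([_midranks(row) for row in m])
    q = _friedman_q(ranks)
    n_arrangements = math.factorial(k) ** n
    if exact is None:
        exact = n_arrangements <= exact_max_cells
    if exact:
        if n_arrangements > 5_000_000:
            raise ValueError("exact Friedman enumeration too large; pass exact=False")
        count = 0
        total = 0
        per_block = [list(itertools.permutations(row)) for row in ranks]
        for combo in itertools.product(*per_block):
            total += 1
            if _friedman_q(np.asarray(combo)) >= q - 1e-12:
                count += 1
        return TestResult(q, count / total, df=k - 1, method="exact-permutation")
    return TestResult(q, float(sps.chi2.sf(q, k - 1)), df=k - 1, method="chi2")


def chisq_homogeneity(table: ProportionTable) -> TestResult:
    """Pearson chi-square test of equal proportions across k groups (df = k-1)."""
    groups = table.groups
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    s = np.array([g[1] for g in groups], dtype=float)
    n = np.array([g[2] for g in groups], dtype=float)
    p_pool = s.sum() / n.sum()
    expected = np.column_stack([n * p_pool, n * (1 - p_pool)])
    if np.any(expected == 0):
        raise ValueError("zero expected count; use an exact test")
    observed = np.column_stack([s, n - s])
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = len(groups) - 1
    return TestResult(stat, float(sps.chi2.sf(stat, df)), df=df, method="pearson")


def two_proportions_chisq(s1: int, n1: int, s2: int, n2: int) -> TestResult:
    """Two-sample proportions chi-square test (unpaired; 1 df)."""
    return chisq_homogeneity(ProportionTable((("a", s1, n1), ("b", s2, n2))))


def marascuillo(table: ProportionTable, alpha: float = 0.05) -> list[dict]:
    """Marascuillo pairwise comparisons after a k-group proportions test.

    Pair (i, j) is significant when |p_i - p_j| exceeds
    sqrt(chi2_{1-alpha, k-1}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j).
    """
    groups = table.groups
    k = len(groups)
    if k < 3:
        raise ValueError("Marascuillo needs >= 3 groups; use two_proportions_chisq")
    crit_root = np.sqrt(sps.chi2.ppf(1 - alpha, k - 1))
    out = []
    for (la, sa, na), (lb, sb, nb) in itertools.combinations(groups, 2):
        pa, pb = sa / na, sb / nb
        rng = crit_root * np.sqrt(pa * (1 - pa) / na + pb * (1 - pb) / nb)
        out.append(
            {
                "pair": (la, lb),
                "diff": abs(pa - pb),
                "critical_range": float(rng),
                "significant": bool(abs(pa - pb) > rng),
            }
        )
    return out


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value (capped at 1)."""
    return min(1.0, p * n_comparisons)
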