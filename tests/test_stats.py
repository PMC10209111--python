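import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from layerphys.stats import (
    ProportionTable,
    bonferroni,
    chisq_homogeneity,
    friedman,
    marascuillo,
    mcnemar,
    rank_sum,
    two_proportions_chisq,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# independent enumeration oracles


def enum_signed_rank_p(diffs):
    """Two-sided signed-rank p by brute enumeration of all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def enum_rank_sum_p(x, y):
    """Two-sided rank-sum p by enumerating all group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:m].sum()
    ws = [sum(ranks[list(c)]) for c in itertools.combinations(range(ranks.size), m)]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def enum_mcnemar_p(b, c):
    """Two-sided exact binomial p from the pmf directly."""
    n = b + c
    pmf = np.array([math.comb(n, k) for k in range(n + 1)], float) / 2**n
    lo = pmf[: b + 1].sum()
    hi = pmf[b:].sum()
    return min(1.0, 2 * min(lo, hi))


def classic_friedman_q(rank_matrix):
    """Classic statistic with the standard tie-correction denominator."""
    r = np.asarray(rank_matrix, float)
    n, k = r.shape
    rj = r.sum(axis=0)
    q0 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
    ties = 0.0
    for row in r:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    corr = 1 - ties / (n * k * (k**2 - 1))
    return 0.0 if corr == 0 else q0 / corr


def enum_friedman_p(matrix):
    """Exact permutation p over all within-block rank orderings."""
    r = np.vstack([sps.rankdata(row) for row in np.asarray(matrix, float)])
    q_obs = classic_friedman_q(r)
    total = 0
    count = 0
    for combo in itertools.product(*[list(itertools.permutations(row)) for row in r]):
        total += 1
        if classic_friedman_q(np.asarray(combo)) >= q_obs - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------


class TestWilcoxonSignedRank:
    def test_all_positive_small_n(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]).p == pytest.approx(0.0625)

    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank(np.zeros(8))
        assert res.p == 1.0 and "degenerate" in res.method

    def test_matches_enumeration_on_random_small_inputs(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            d = rng.integers(-4, 5, n).astype(float)  # integer diffs force ties
            assert wilcoxon_signed_rank(d).p == pytest.approx(enum_signed_rank_p(d))

    def test_exact_and_normal_agree_at_switch_point(self, rng):
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 25)
            exact = wilcoxon_signed_rank(d, exact_max_n=25).p
            approx = wilcoxon_signed_rank(d, exact_max_n=0).p
            assert abs(exact - approx) < 0.01

    @given(st.lists(st.integers(-5, 5), min_size=5, max_size=10))
    def test_p_in_unit_interval_and_sign_flip_invariant(self, diffs):
        d = np.asarray(diffs, float)
        p = wilcoxon_signed_rank(d).p
        assert 0 <= p <= 1
        assert wilcoxon_signed_rank(-d).p == pytest.approx(p)


class TestRankSum:
    def test_separated_samples_small_n(self):
        assert rank_sum([1, 2, 3], [4, 5, 6]).p == pytest.approx(0.1)

    def test_identical_samples(self):
        assert rank_sum([1, 2, 3], [1, 2, 3]).p == 1.0

    def test_matches_enumeration_on_random_small_inputs(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 7))
            x = rng.integers(0, 6, m).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            assert rank_sum(x, y).p == pytest.approx(enum_rank_sum_p(x, y))

    def test_exact_and_normal_agree_at_m_n_ten(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.4, 1, 10)
            exact = rank_sum(x, y, exact_max_n=20).p
            approx = rank_sum(x, y, exact_max_n=0).p
            assert abs(exact - approx) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])

    def test_symmetric_under_group_swap(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 5)
        assert rank_sum(x, y).p == pytest.approx(rank_sum(y, x).p)


class TestMcNemar:
    def test_exact_binomial_example(self):
        assert mcnemar(8, 2).p == pytest.approx(112 / 1024)

    def test_balanced_discordance_is_one(self):
        assert mcnemar(6, 6).p == 1.0

    def test_no_discordant_pairs_flagged(self):
        res = mcnemar(0, 0)
        assert res.p == 1.0 and "degenerate" in res.method

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            b = int(rng.integers(0, 13))
            c = int(rng.integers(0, 13))
            if b + c == 0:
                continue
            assert mcnemar(b, c).p == pytest.approx(enum_mcnemar_p(b, c))

    def test_exact_and_corrected_chi2_agree_at_25_pairs(self):
        for b in range(5, 21):
            c = 25 - b
            exact = enum_mcnemar_p(b, c)
            approx = mcnemar(b, c).p  # b+c=25 uses the chi-square branch
            assert abs(exact - approx) < 0.02


class TestFriedman:
    def test_identical_orderings_exact(self):
        m = [[1, 2, 3], [1, 2, 3], [1, 2, 3]]
        res = friedman(m, exact=True)
        assert res.statistic == pytest.approx(6.0)
        assert res.p == pytest.approx(6 / 216)

    def test_constant_rows_give_zero(self):
        res = friedman(np.ones((4, 3)), exact=False)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_statistic_matches_classic_tie_corrected_formula(self, rng):
        for _ in range(20):
            m = rng.integers(0, 4, size=(5, 3)).astype(float)
            ranks = np.vstack([sps.rankdata(r) for r in m])
            if np.allclose(classic_friedman_q(ranks), 0):
                continue
            assert friedman(m, exact=False).statistic == pytest.approx(
                classic_friedman_q(ranks)
            )

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(5):
            m = rng.normal(size=(3, 3))
            assert friedman(m, exact=True).p == pytest.approx(enum_friedman_p(m))

    def test_null_p_roughly_uniform(self, rng):
        ps = [
            friedman(rng.normal(size=(10, 3)), exact=False).p for _ in range(400)
        ]
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert 0.02 <= rate <= 0.09

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            friedman(np.ones((1, 3)))
        with pytest.raises(ValueError):
            friedman(np.ones((3, 2)))


class TestChisqHomogeneity:
    def test_equal_proportions_give_zero(self):
        res = chisq_homogeneity(ProportionTable((("a", 30, 100), ("b", 30, 100))))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_scipy_contingency(self):
        table = ProportionTable((("a", 90, 100), ("b", 50, 100)))
        res = chisq_homogeneity(table)
        obs = np.array([[90, 10], [50, 50]])
        ref = sps.chi2_contingency(obs, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_matches_exact_permutation_null(self):
        """Against the full conditional (hypergeometric) permutation null."""
        s1, n1, s2, n2 = 230, 500, 262, 500
        res = two_proportions_chisq(s1, n1, s2, n2)
        S, N = s1 + s2, n1 + n2
        p_exact = 0.0
        for a in range(max(0, S - n2), min(n1, S) + 1):
            stat = chisq_homogeneity(
                ProportionTable((("a", a, n1), ("b", S - a, n2)))
            ).statistic
            if stat >= res.statistic - 1e-9:
                p_exact += sps.hypergeom.pmf(a, N, S, n1)
        assert abs(p_exact - res.p) < 0.01

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError, match="exact"):
            chisq_homogeneity(ProportionTable((("a", 0, 10), ("b", 0, 10))))


class TestMarascuillo:
    def test_worked_example(self):
        table = ProportionTable((("a", 50, 100), ("b", 50, 100), ("c", 90, 100)))
        out = {tuple(r["pair"]): r for r in marascuillo(table)}
        assert out[("a", "c")]["significant"]
        assert out[("a", "c")]["critical_range"] == pytest.approx(0.1427, abs=1e-3)
        assert not out[("a", "b")]["significant"]

    def test_identical_groups_nothing_significant(self):
        table = ProportionTable(tuple((f"g{i}", 40, 100) for i in range(4)))
        assert not any(r["significant"] for r in marascuillo(table))

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            marascuillo(ProportionTable((("a", 1, 10), ("b", 2, 10))))

    def test_familywise_error_controlled_under_null(self, rng):
        p0, n, reps = 0.4, 100, 2000
        fw = 0
        for _ in range(reps):
            succ = rng.binomial(n, p0, size=3)
            table = ProportionTable(tuple((f"g{i}", int(s), n) for i, s in enumerate(succ)))
            fw += any(r["significant"] for r in marascuillo(table, alpha=0.05))
        assert fw / reps <= 0.05 + 0.02


def test_bonferroni_caps_at_one():
    assert bonferroni(0.03, 3) == pytest.approx(0.09)
    assert bonferroni(0.4, 5) == 1.0
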