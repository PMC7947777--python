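from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macrosyn import stats
from oracles import binom_tail_ge, ranksum_exact_p


class TestBinomialTest:
    @pytest.mark.parametrize(
        "k,n,p,expected",
        [
            (5, 5, 1.0, 1.0),  # success certain
            (0, 10, 0.0, 1.0),  # zero rate, zero successes
        ],
    )
    def test_degenerate_tails(self, k, n, p, expected):
        assert stats.binomial_test(k, n, p).p_value == pytest.approx(expected)

    def test_matches_rational_tail_sum(self):
        # frozen from the exact rational oracle: P(X>=20 | n=50, p=0.1)
        expected = float(binom_tail_ge(20, 50, Fraction(1, 10)))
        res = stats.binomial_test(20, 50, 0.1, sided="one-greater")
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(2.3685993581841863e-08, rel=1e-9)

    def test_exhaustive_small_n(self):
        # equality with the pmf tail sum for every (k, n<=25) at several p
        for p_frac in (Fraction(1, 10), Fraction(1, 2), Fraction(7, 10)):
            p = float(p_frac)
            for n in range(1, 26):
                for k in range(0, n + 1):
                    expected = float(binom_tail_ge(k, n, p_frac))
                    got = stats.binomial_test(k, n, p).p_value
                    assert got == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            stats.binomial_test(6, 5, 0.5)
        with pytest.raises(ValueError):
            stats.binomial_test(1, 5, 1.5)
        with pytest.raises(ValueError):
            stats.binomial_test(0, 0, 0.5)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.5], [0.5]),
            ([1.0, 1.0], [1.0, 1.0]),
            # hand step-up: p_(i) * n/i then monotone minimum from the right
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_known_values(self, raw, expected):
        assert list(stats.bh_adjust(raw).adjusted) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_order_invariant_and_dominating(self, pvals, rnd):
        adj = list(stats.bh_adjust(pvals).adjusted)
        assert all(a >= p for a, p in zip(adj, pvals))
        assert all(a <= 1.0 for a in adj)
        # permuting the input permutes the output identically
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj_perm = list(stats.bh_adjust([pvals[i] for i in perm]).adjusted)
        assert adj_perm == pytest.approx([adj[i] for i in perm])


class TestWilcoxonRankSum:
    def test_identical_groups_no_shift(self):
        res = stats.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_most_extreme_small_case(self):
        # enumeration over C(6,3)=20 assignments: most extreme split
        res = stats.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], sided="two")
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "wilcoxon-exact"

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 6):
            for n2 in range(1, 11 - n1):
                x = rng.integers(0, 4, size=n1).astype(float)
                y = rng.integers(0, 4, size=n2).astype(float)
                for sided in ("two", "one-greater"):
                    got = stats.wilcoxon_rank_sum(x, y, sided=sided)
                    assert got.p_value == pytest.approx(
                        ranksum_exact_p(x, y, sided=sided)
                    ), (x, y, sided)

    def test_normal_approximation_large_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 50)
        y = rng.normal(0.0, 1.0, 60)
        res = stats.wilcoxon_rank_sum(x, y, sided="one-greater")
        assert res.method == "wilcoxon-normal"
        assert res.p_value < 1e-4

    def test_statistic_matches_r_convention(self):
        # W = rank sum of x minus n1(n1+1)/2 (Mann-Whitney U of x)
        res = stats.wilcoxon_rank_sum([10, 20], [1, 2, 3])
        assert res.statistic == pytest.approx(6.0)


class TestPearsonR:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert stats.pearson_r(x, x).statistic == pytest.approx(1.0)
        assert stats.pearson_r(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        r_direct = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert stats.pearson_r(x, y).statistic == pytest.approx(r_direct, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            stats.pearson_r([1, 2], [1, 2])
        with pytest.raises(ValueError):
            stats.pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            stats.pearson_r([1, 2, 3], [1, 2])


class TestProportionChisq:
    def test_equal_proportions_zero(self):
        assert stats.proportion_chisq(10, 100, 10, 100).statistic == pytest.approx(0.0)

    def test_matches_hand_formula(self):
        # direct 2x2 chi-square without continuity correction
        k1, n1, k2, n2 = 30, 100, 10, 100
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        chi2 = float(((table - expected) ** 2 / expected).sum())
        res = stats.proportion_chisq(k1, n1, k2, n2)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.method == "chisq-2x2"

    def test_zero_cells_error(self):
        with pytest.raises(ValueError):
            stats.proportion_chisq(0, 0, 1, 10)
        with pytest.raises(ValueError):
            stats.proportion_chisq(0, 10, 0, 10)  # zero successes column


class TestEmpiricalP:
    def test_extreme_observation(self):
        null = list(range(10_000))
        p_empirical, p_cons = stats.empirical_p(10_001, null)
        assert p_empirical == 0.0
        assert p_cons == pytest.approx(1 / 10_001)

    def test_observation_below_all(self):
        p_empirical, _ = stats.empirical_p(-1.0, [0.0, 1.0, 2.0])
        assert p_empirical == 1.0

    def test_median_observation_and_accounting(self):
        rng = np.random.default_rng(3)
        null = rng.normal(size=10_001)
        obs = float(np.median(null))
        p_empirical, _ = stats.empirical_p(obs, null)
        assert p_empirical == pytest.approx(0.5, abs=0.01)
        # tail accounting: #(>=obs) + #(<obs) = N
        n_lt = int(np.count_nonzero(null < obs))
        assert p_empirical + n_lt / null.size == pytest.approx(1.0)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            stats.empirical_p(1.0, [])


class TestPercentChange:
    @pytest.mark.parametrize(
        "old,new,nd,expected",
        [(0.03, 0.53, 0, 1667), (10, 10, 0, 0), (395.14, 525.80, 0, 33)],
    )
    def test_values(self, old, new, nd, expected):
        assert stats.percent_change(old, new, nd) == expected

    def test_nonpositive_old(self):
        with pytest.raises(ValueError):
            stats.percent_change(0, 5)
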