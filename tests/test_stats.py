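"""Rank tests against full-enumeration oracles and distributional checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asc_time.stats import (
    benjamini_hochberg,
    mann_whitney_u,
    spearman,
    wilcoxon_signed_rank,
)

from _oracles import mann_whitney_p_enumeration, wilcoxon_p_enumeration


class TestWilcoxonSignedRank:
    def test_all_equal_pairs_degenerate(self):
        res = wilcoxon_signed_rank([(1.0, 1.0)] * 5)
        assert res.p_value == 1.0
        assert res.n_effective == 0
        assert res.warning is not None

    def test_six_positive_differences_exact_p(self):
        # all 2^6 sign assignments; one-tailed mass 1/64, doubled
        pairs = [(float(i), 0.0) for i in range(1, 7)]
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)
        assert res.statistic == 21.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=10), rng.normal(size=10)
        p1 = wilcoxon_signed_rank(list(zip(a, b))).p_value
        p2 = wilcoxon_signed_rank(list(zip(b, a))).p_value
        assert p1 == pytest.approx(p2)

    def test_zero_differences_dropped_from_n_effective(self):
        pairs = [(1.0, 1.0), (2.0, 1.0), (3.0, 1.0), (4.0, 1.0)]
        assert wilcoxon_signed_rank(pairs).n_effective == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_equals_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.normal(size=n)
        a = d
        b = np.zeros(n)
        res = wilcoxon_signed_rank(list(zip(a, b)))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_p_enumeration(d))

    def test_ties_fall_back_to_normal_approximation(self):
        pairs = [(2.0, 1.0), (3.0, 2.0), (5.0, 1.0), (1.0, 6.0)]
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "normal_approx"
        assert 0.0 <= res.p_value <= 1.0

    def test_large_n_switches_to_normal_approximation(self):
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.normal(size=40), rng.normal(size=40)))
        assert wilcoxon_signed_rank(pairs).method == "normal_approx"

    def test_agrees_with_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(5)
        d = rng.normal(size=12)
        ours = wilcoxon_signed_rank([(x, 0.0) for x in d])
        theirs = scipy_wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(theirs.pvalue)


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_groups_exact_p(self):
        # U = 0; 2 / C(6,3) = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=6), rng.normal(size=8)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_equals_subset_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n1 = int(rng.integers(2, 8))
        n2 = int(rng.integers(2, 8))
        a, b = rng.normal(size=n1), rng.normal(size=n2)
        res = mann_whitney_u(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mann_whitney_p_enumeration(a, b))

    def test_agrees_with_scipy(self):
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(9)
        a, b = rng.normal(size=5), rng.normal(size=7)
        ours = mann_whitney_u(a, b)
        theirs = scipy_mwu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(theirs.pvalue)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)
        res = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.statistic == pytest.approx(-1.0)

    def test_textbook_rho_from_rank_differences(self):
        # rho = 1 - 6 * sum(d^2) / (n (n^2 - 1)) with sum(d^2) = 4
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.statistic == pytest.approx(0.8)
        assert res.method == "permutation"

    def test_exact_p_matches_scipy_rho_enumeration(self):
        from itertools import permutations

        from scipy.stats import spearmanr

        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho_obs = spearmanr(x, y).statistic
        rhos = [spearmanr(x, list(p)).statistic for p in permutations(y)]
        expected = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in rhos])
        assert spearman(x, y).p_value == pytest.approx(expected)

    def test_constant_vector_warns_not_raises(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.statistic)
        assert res.warning is not None

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        res = spearman(x, x + rng.normal(size=30))
        assert res.method == "t_approx"
        assert 0.0 <= res.p_value <= 1.0


class TestRankInvariance:
    """p-values of rank tests are invariant under monotone transforms."""

    # integer data keeps the monotone maps exact in floating point,
    # so rank structure is provably preserved

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
        min_size=4, max_size=12,
    ))
    def test_wilcoxon_invariant_under_positive_scaling(self, pairs):
        # positive affine maps preserve differences' signs and rank order
        base = wilcoxon_signed_rank(pairs).p_value
        scaled = wilcoxon_signed_rank(
            [(3.0 * a + 7.0, 3.0 * b + 7.0) for a, b in pairs]).p_value
        assert base == pytest.approx(scaled)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-10, 10), min_size=2, max_size=10),
        st.lists(st.integers(-10, 10), min_size=2, max_size=10),
    )
    def test_mann_whitney_invariant_under_cubic_map(self, a, b):
        base = mann_whitney_u(a, b).p_value
        transformed = mann_whitney_u(
            [x ** 3 for x in a], [x ** 3 for x in b]).p_value
        assert base == pytest.approx(transformed)


class TestTypeIError:
    def test_empirical_size_near_nominal_alpha(self):
        """Exchangeable null pairs: rejection rate at alpha=0.05 stays in
        [0.03, 0.07] over 10,000 simulations."""
        rng = np.random.default_rng(20220812)
        n_sim, n_pairs = 10_000, 20
        diffs = rng.normal(size=(n_sim, n_pairs))
        rejections = 0
        for row in diffs:
            res = wilcoxon_signed_rank([(x, 0.0) for x in row])
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


def test_benjamini_hochberg_is_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    q = benjamini_hochberg(p)
    assert all(qi >= pi for qi, pi in zip(q, p))
    assert all(0 <= qi <= 1 for qi in q)
    assert q == sorted(q)
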