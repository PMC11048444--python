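"""Level filtering: SET, correlation t-test, Bonferroni, base selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hpca import levelstats as ls
from hpca import tree as tr


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.001, 2046, 0.001 / 2046), (0.05, 1, 0.05), (0.01, 100, 1e-4)],
    )
    def test_division(self, alpha, m, expected):
        got = ls.bonferroni_alpha(alpha, m)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got * m == pytest.approx(alpha, rel=1e-12)

    def test_printed_example_magnitude(self):
        # 0.001 over 2 x 1023 tests is ~4.9e-7
        assert ls.bonferroni_alpha(0.001, 2046) == pytest.approx(4.9e-7, rel=0.01)

    @pytest.mark.parametrize("alpha, m", [(0.0, 10), (1.0, 10), (0.05, 0)])
    def test_domain_errors(self, alpha, m):
        with pytest.raises(ValueError):
            ls.bonferroni_alpha(alpha, m)


class TestSetTest:
    def test_zero_eigenvalue_certain_rejection(self):
        res = ls.set_test(0.0, gamma=0.4, K=300, alpha=1e-6)
        assert res.reject_H0 and res.p_value == 0.0 and res.underflow

    def test_boundary_is_coin_flip(self):
        res = ls.set_test(0.4, gamma=0.4, K=300, alpha=4.9e-7)
        assert res.p_value == pytest.approx(0.5)
        assert not res.reject_H0

    def test_worked_example_rejects(self):
        """lambda2=0.15 at gamma=0.4, K=300: the rejection boundary
        gamma - z_a * lambda2 * sqrt(2/299) ~ 0.34 exceeds 0.15."""
        alpha = 0.001 / 2046
        res = ls.set_test(0.15, gamma=0.4, K=300, alpha=alpha)
        assert res.reject_H0
        # normal-quantile oracle for the same decision
        z_a = stats.norm.isf(alpha)
        boundary = 0.4 - z_a * 0.15 * np.sqrt(2 / 299)
        assert boundary > 0.15
        assert boundary == pytest.approx(0.34, abs=0.01)
        # decision rule and p-value agree
        assert (res.p_value < alpha) == (0.15 < boundary)

    def test_monotone_in_lambda2(self):
        """Rejection region is downward-closed in lambda2."""
        alpha = 1e-5
        lams = np.linspace(0.01, 0.8, 50)
        ps = [ls.set_test(l, 0.4, 200, alpha).p_value for l in lams]
        assert (np.diff(ps) >= -1e-15).all()
        rejected = [p < alpha for p in ps]
        # once acceptance starts it never reverts
        assert rejected == sorted(rejected, reverse=True)

    def test_insufficient_observations(self):
        with pytest.raises(ValueError):
            ls.set_test(0.1, 0.4, K=2, alpha=0.01)


class TestCorrTest:
    def test_null_centre(self):
        res = ls.corr_test(0.0, K=300, alpha=0.05)
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(0.5)
        assert not res.significant

    def test_strong_negative_correlation(self):
        res = ls.corr_test(-0.99, K=300, alpha=0.05)
        assert res.p_value > 0.99
        assert not res.significant

    def test_t_statistic_oracle(self):
        res = ls.corr_test(0.5, K=102, alpha=0.001)
        assert res.t_stat == pytest.approx(10 * 0.5 / np.sqrt(0.75), rel=1e-12)
        assert res.t_stat == pytest.approx(5.7735, abs=1e-4)
        assert res.p_value == pytest.approx(stats.t.sf(5.7735, 100), rel=1e-3)
        assert res.df == 100

    @pytest.mark.parametrize("r, p", [(1.0, 0.0), (-1.0, 1.0)])
    def test_perfect_correlations(self, r, p):
        assert ls.corr_test(r, 50, 0.01).p_value == p

    def test_p_strictly_decreasing_in_r(self):
        rs = np.linspace(-0.5, 0.9, 29)
        ps = [ls.corr_test(r, 40, 0.05).p_value for r in rs]
        assert (np.diff(ps) < 0).all()

    def test_negative_r_never_below_half(self):
        for r in (-0.9, -0.5, -0.1, 0.0):
            assert ls.corr_test(r, 40, 0.05).p_value >= 0.5

    def test_type_one_error_calibrated(self, rng):
        """Null calibration: independent Gaussian pairs produce a
        false-positive rate within binomial tolerance of alpha."""
        K, reps, alpha = 50, 100_000, 0.01
        x = rng.standard_normal((reps, K))
        y = rng.standard_normal((reps, K))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = np.einsum("ij,ij->i", xc, yc) / (
            np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
        )
        t = np.sqrt(K - 2) * r / np.sqrt(1 - r**2)
        fp = (stats.t.sf(t, K - 2) < alpha).mean()
        assert fp <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    lam=st.floats(0.0, 1.0),
    gamma=st.floats(0.05, 1.0),
    K=st.integers(3, 1000),
)
def test_set_decision_matches_boundary_form(lam, gamma, K):
    """The p-value rule is equivalent to the closed-form rejection boundary
    lambda2 < gamma - z_alpha * lambda2 * sqrt(2/(K-1))."""
    alpha = 1e-4
    res = ls.set_test(lam, gamma, K, alpha)
    z_a = stats.norm.isf(alpha)
    boundary = gamma - z_a * lam * np.sqrt(2.0 / (K - 1))
    assert res.reject_H0 == (lam < boundary)


def _duplicate_tree(rng, n_pairs=6, K=120):
    """2*n_pairs variables: n_pairs duplicated sources. The first n_pairs
    merges are exact duplicates (r=1); later merges join distinct sources."""
    src = rng.standard_normal((n_pairs, K))
    X = np.vstack([np.vstack([s, s]) for s in src])
    return tr.build_tree(X)


class TestBaseLevelSelection:
    def test_duplicate_prefix_found_exactly(self, rng):
        tree = _duplicate_tree(rng)
        alpha = ls.bonferroni_alpha(0.001, 2 * (tree.n_leaves - 1))
        base = ls.select_base_level(tree, gamma=0.4, alpha=alpha)
        assert base == 6  # one redundant merge per duplicated pair

    def test_no_rejections_warns_and_returns_zero(self, rng):
        X = rng.standard_normal((10, 60))
        tree = tr.build_tree(X)
        with pytest.warns(RuntimeWarning, match="base level 0"):
            base = ls.select_base_level(tree, gamma=0.01, alpha=1e-8)
        assert base == 0

    def test_isolated_rejections_do_not_extend_prefix(self):
        """A later SET rejection beyond the first acceptance must not move
        the base level (constructed eigenvalue sequence)."""
        class FakeNode:
            def __init__(self, level, lam2):
                self.level = level
                self.lambda2 = lam2
                self.merge_similarity = 1 - lam2

        class FakeTree:
            n_dims = 300
            n_leaves = 6
            nodes = [FakeNode(1, 0.01), FakeNode(2, 0.01), FakeNode(3, 0.9),
                     FakeNode(4, 0.01), FakeNode(5, 0.9)]

        base = ls.select_base_level(FakeTree(), gamma=0.4, alpha=1e-6)
        assert base == 2


class TestFilterLevels:
    def test_white_noise_flags_everything_unrelated(self, rng):
        """Independent variables: no redundant prefix, and essentially every
        level fails the correlation test at the tiny per-test alpha."""
        X = rng.standard_normal((40, 200))
        tree = tr.build_tree(X)
        with pytest.warns(RuntimeWarning):
            rep = ls.filter_levels(tree, gamma=0.4, alpha_fwe=0.001)
        assert rep.base_level == 0
        n_levels = tree.n_levels
        # binomial tolerance around all-unrelated
        assert len(rep.unrelated_levels) >= n_levels - 3
        assert rep.n_tests == 2 * 39
        assert rep.alpha_per_test == pytest.approx(0.001 / 78)

    def test_duplicate_fixture_partition(self, rng):
        tree = _duplicate_tree(rng, n_pairs=5, K=400)
        rep = ls.filter_levels(tree, gamma=0.4, alpha_fwe=0.001)
        assert rep.base_level == 5
        assert rep.redundant_levels == range(1, 6)
        levels = set(rep.significant_levels) | set(rep.unrelated_levels)
        assert levels == set(range(6, tree.n_levels + 1))
        table = rep.table
        assert set(table.columns) >= {"level", "r", "lambda2", "p_set", "p_corr", "flag"}
        assert (table.loc[table.level <= 5, "flag"] == "redundant").all()

    def test_report_counts_consistent(self, rng):
        tree = _duplicate_tree(rng, n_pairs=4, K=300)
        rep = ls.filter_levels(tree, 0.4, 0.001)
        assert rep.n_active == tree.n_leaves - rep.base_level
        assert rep.n_tests == 2 * (tree.n_leaves - 1)
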