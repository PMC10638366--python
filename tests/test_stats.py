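"""Statistical toolkit against independent oracles.

Oracles: a normal-equations matrix solve (and statsmodels) for OLS, full
permutation enumeration for the exact Wilcoxon path, a seeded permutation
sample for the approximate path, and values frozen from R 4.3.3
(``shapiro.test``, ``t.test``) for the reference fixtures.
"""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bolipore.stats import (
    manual_auto_agreement,
    ols_fit,
    shapiro_wilk,
    t_test,
    wilcoxon_test,
)


def ols_normal_equations(x, y):
    """Independent OLS oracle: solve (XᵀX)β = Xᵀy and the matrix SE formula."""
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(x) - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


class TestOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_against_normal_equations_on_random_fixtures(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(size=n) * rng.uniform(0.5, 20)
            y = rng.normal(2, 5) * x + rng.normal(size=n) * rng.uniform(0.1, 3)
            fit = ols_fit(x, y)
            beta, se = ols_normal_equations(x, y)
            assert fit.slope == pytest.approx(beta[0], abs=1e-10)
            assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
            assert fit.slope_se == pytest.approx(se[0], rel=1e-10)
            assert fit.intercept_se == pytest.approx(se[1], rel=1e-10)

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 25)
        y = 3.0 * x - 4.0 + rng.normal(0, 2, 25)
        fit = ols_fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.r_squared == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.p_slope == pytest.approx(ref.pvalues[1], rel=1e-8)

    def test_guards(self):
        with pytest.raises(ValueError, match="3 points"):
            ols_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            ols_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestTTest:
    def test_identical_groups(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # frozen from R: t.test(c(1,2,3), c(2,3,4), var.equal=TRUE)
        res = t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], variant="student")
        assert res.statistic == pytest.approx(-1.224745, abs=1e-6)
        assert res.p == pytest.approx(0.287864, abs=1e-6)
        assert res.method == "student_t"

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 20),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.2, 15)
        p0 = t_test(a, b).p
        p1 = t_test(a * scale + shift, b * scale + shift).p
        assert p1 == pytest.approx(p0, rel=1e-9)


def wilcoxon_enumeration_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of all group
    assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    ws = [sum(c) for c in itertools.combinations(ranks, n1)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_enumeration_examples(self):
        res = wilcoxon_test([1.0, 2.0], [3.0, 4.0])
        assert res.method == "wilcoxon_exact"
        assert res.statistic == 3.0  # rank sum of {1,2}
        assert res.p == pytest.approx(1.0 / 3.0)
        res2 = wilcoxon_test([1.0, 4.0], [2.0, 3.0])
        assert res2.statistic == 5.0  # equals the null mean n1(n+1)/2
        assert res2.p == pytest.approx(1.0)

    def test_exact_path_equals_full_enumeration_exhaustively(self):
        """For every tie-free configuration with n1+n2 <= 10 the exact path
        matches full enumeration."""
        rng = np.random.default_rng(99)
        for n in range(2, 11):
            for n1 in range(1, n):
                for comb in itertools.combinations(range(n), n1):
                    vals = np.arange(1.0, n + 1)
                    a = vals[list(comb)]
                    b = np.delete(vals, list(comb))
                    res = wilcoxon_test(a, b)
                    assert res.method == "wilcoxon_exact"
                    assert res.p == pytest.approx(wilcoxon_enumeration_p(a, b), abs=1e-12)

    def test_normal_approximation_close_to_permutation_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.4, 1.0, 35)
        res = wilcoxon_test(a, b)
        assert res.method == "wilcoxon_normal"
        pooled = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        w_obs = ranks[: len(a)].sum()
        mu = len(a) * (len(pooled) + 1) / 2.0
        perm = np.empty(10_000)
        for i in range(10_000):
            rng.shuffle(ranks)
            perm[i] = ranks[: len(a)].sum()
        p_perm = min(1.0, 2.0 * min(np.mean(perm <= w_obs), np.mean(perm >= w_obs)))
        assert res.p == pytest.approx(p_perm, abs=0.01)

    def test_ties_force_normal_path(self):
        res = wilcoxon_test([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "wilcoxon_normal"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(size=7)
        if np.unique(np.concatenate([a, b])).size < 15:
            return
        p0 = wilcoxon_test(a, b).p
        p1 = wilcoxon_test(np.exp(a), np.exp(b)).p
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_test([], [1.0])


class TestShapiroWilk:
    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_reference_fixture_matches_r(self):
        # frozen from R: shapiro.test(c(2.1,3.4,1.9,5.6,4.2,3.3,2.8,4.9,3.7,3.1))
        x = [2.1, 3.4, 1.9, 5.6, 4.2, 3.3, 2.8, 4.9, 3.7, 3.1]
        res = shapiro_wilk(x)
        assert res.statistic == pytest.approx(0.9659709894, abs=1e-3)
        assert res.p == pytest.approx(0.8511853464, abs=5e-3)

    def test_type_one_error_rate(self):
        """Rejection rate at α=0.05 over 1,000 seeded normal samples of
        n=50 stays within [0.03, 0.07]."""
        rng = np.random.default_rng(2718)
        rejections = sum(
            shapiro_wilk(rng.normal(size=50)).p < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestAgreement:
    def test_identical_counts_give_zero_difference(self):
        rep = manual_auto_agreement([100, 120, 90], [100, 120, 90], [60000.0] * 3)
        assert rep.mean_diff_pct == 0.0
        assert rep.max_diff_pct == 0.0

    def test_forced_arithmetic(self):
        rep = manual_auto_agreement([100], [90], [60000.0])
        assert rep.per_specimen_diff_pct[0] == pytest.approx(10.0)

    def test_zero_manual_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            manual_auto_agreement([0, 10], [1, 10], [1.0, 1.0])

    def test_reports_both_t_variants(self):
        rng = np.random.default_rng(5)
        manual = rng.integers(200, 300, 20)
        auto = manual + rng.integers(-8, 9, 20)
        areas = np.full(20, 60_000.0)
        rep = manual_auto_agreement(manual, auto, areas)
        assert rep.t_unpaired.method == "student_t"
        assert rep.t_paired.method == "student_t_paired"
        assert 0 <= rep.min_diff_pct <= rep.mean_diff_pct <= rep.max_diff_pct
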