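"""Permutation plans, ASCA/VASCA tests, univariate p-values and BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasca import (
    ModelTerms,
    PermutationPlan,
    asca_test,
    bh_adjust,
    build_coding,
    fdr_test,
    fit_glm,
    full_factorial,
    univariate_pvalues,
    variable_statistics,
    vasca_test,
)
from vasca.permutation import permutation_pvalue, permuted_column_ssq

from conftest import random_balanced_problem


def small_problem(seed=0, n_vars=6, levels=(3, 2), replicates=2):
    rng = np.random.default_rng(seed)
    X, design, coding = random_balanced_problem(
        rng, levels=levels, replicates=replicates, n_vars=n_vars
    )
    return X - X.mean(axis=0), coding


class TestPermutationPlan:
    def test_same_seed_same_permutations(self):
        a = PermutationPlan(50, seed=3).draw(10)
        b = PermutationPlan(50, seed=3).draw(10)
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        a = PermutationPlan(50, seed=3).draw(10)
        b = PermutationPlan(50, seed=4).draw(10)
        assert not np.array_equal(a, b)

    def test_explicit_permutations_validated(self):
        plan = PermutationPlan(2, permutations=np.array([[0, 1], [1, 0]]))
        np.testing.assert_array_equal(plan.draw(2), [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="shape"):
            plan.draw(3)

    def test_zero_perms_rejected(self):
        with pytest.raises(ValueError):
            PermutationPlan(0)


class TestPermutedStats:
    def test_identity_permutation_reproduces_observed(self):
        X, coding = small_problem()
        plan = PermutationPlan(1, permutations=np.arange(X.shape[0])[None, :])
        stats = permuted_column_ssq(X, coding, "A", plan)
        np.testing.assert_allclose(
            stats.effect_ssq[0], stats.observed_effect_ssq, rtol=1e-12
        )
        np.testing.assert_allclose(
            stats.resid_ssq[0], stats.observed_resid_ssq, rtol=1e-10
        )

    def test_observed_matches_direct_fit(self):
        X, coding = small_problem()
        plan = PermutationPlan(3, seed=0)
        stats = permuted_column_ssq(X, coding, "A", plan)
        d = fit_glm(X, coding)
        np.testing.assert_allclose(
            stats.observed_effect_ssq, np.sum(d.effects["A"] ** 2, axis=0),
            rtol=1e-10,
        )
        np.testing.assert_allclose(
            stats.variable_stats("f_ratio", observed=True),
            variable_statistics(d, "A", "f_ratio"),
            rtol=1e-10,
        )

    def test_same_seed_bit_identical(self):
        X, coding = small_problem()
        s1 = permuted_column_ssq(X, coding, "A", PermutationPlan(20, seed=5))
        s2 = permuted_column_ssq(X, coding, "A", PermutationPlan(20, seed=5))
        np.testing.assert_array_equal(s1.effect_ssq, s2.effect_ssq)

    def test_null_mean_f_matches_f_distribution(self):
        """Permuted per-variable F-ratios average to df_E/(df_E - 2) on null
        normal data (the F-distribution mean): df_E = 38 -> about 1.056."""
        rng = np.random.default_rng(12)
        design = full_factorial([2], 20, names=["g"])  # N = 40, df_E = 38
        coding = build_coding(design, ModelTerms(("g",)))
        X = rng.standard_normal((40, 20))
        X -= X.mean(axis=0)
        stats = permuted_column_ssq(X, coding, "g", PermutationPlan(3000, seed=1))
        f = stats.variable_stats("f_ratio")
        assert f.mean() == pytest.approx(38 / 36, abs=0.03)


class TestAscaTest:
    def test_pvalue_from_direct_count(self):
        assert permutation_pvalue(5.0, np.array([1.0, 2.0, 3.0])) == pytest.approx(
            1 / 4
        )

    def test_boundary_all_draws_exceed(self):
        assert permutation_pvalue(0.0, np.array([0.5, 0.0, 1.0])) == 1.0

    def test_ties_count_as_exceedances(self):
        assert permutation_pvalue(2.0, np.array([2.0, 2.0, 1.0])) == pytest.approx(
            3 / 4
        )

    def test_pvalue_bounds(self):
        X, coding = small_problem()
        res = asca_test(X, coding, "A", "f_ratio", PermutationPlan(49, seed=2))
        assert 1 / 50 <= res.p_value <= 1.0

    @pytest.mark.parametrize("kind", ["ssq", "f_ratio", "pc2_ssq"])
    def test_statistic_kinds_run(self, kind):
        X, coding = small_problem()
        res = asca_test(X, coding, "A", kind, PermutationPlan(30, seed=2))
        assert res.statistic >= 0
        assert res.null_draws.shape == (30,)


class TestVascaTest:
    def test_curve_endpoint_bit_equal_to_asca(self):
        """The p-curve at m = M is bit-identical to the ASCA p-value under a
        shared permutation plan."""
        for seed in range(5):
            X, coding = small_problem(seed=seed, n_vars=7)
            plan = PermutationPlan(99, seed=seed + 100)
            stats = permuted_column_ssq(X, coding, "A", plan)
            a = asca_test(X, coding, "A", "f_ratio", stats=stats)
            v = vasca_test(X, coding, "A", "f_ratio", stats=stats)
            assert v.p_curve[-1] == a.p_value

    def test_reordering_happens_inside_each_permutation(self):
        """Null curves are built from each permutation's own best variables:
        with re-sorting, every null curve is non-increasing in the
        per-variable statistic it accumulates, and the m=1 null draw equals
        the permutation's maximum statistic."""
        X, coding = small_problem(n_vars=5)
        plan = PermutationPlan(40, seed=9)
        stats = permuted_column_ssq(X, coding, "A", plan)
        v = vasca_test(X, coding, "A", "ssq", stats=stats, keep_null=True)
        best = stats.variable_stats("ssq").max(axis=1)
        np.testing.assert_allclose(v.null_curves[:, 0], best, rtol=1e-12)

    def test_strong_signal_selected(self):
        """Two columns carrying a big level offset lead the ordering and are
        selected; the observed cumulative beats every permuted curve."""
        rng = np.random.default_rng(21)
        design = full_factorial([2], 10, names=["g"])
        coding = build_coding(design, ModelTerms(("g",)))
        n = design.n_obs
        offs = np.where(design.codes["g"] == 0, 3.0, -3.0)
        X = np.column_stack([
            offs + 0.1 * rng.standard_normal(n),
            offs + 0.1 * rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        X -= X.mean(axis=0)
        v = vasca_test(X, coding, "g", "f_ratio",
                       PermutationPlan(200, seed=4), alpha=0.05, keep_null=True)
        assert v.selected_m >= 2
        assert set(v.order[:2]) == {0, 1}
        assert np.all(v.cumulative[1] > v.null_curves[:, 1])

    def test_selection_rule_largest_significant_m(self):
        X, coding = small_problem()
        v = vasca_test(X, coding, "A", "f_ratio", PermutationPlan(60, seed=3),
                       alpha=0.5)
        hits = np.nonzero(v.p_curve < 0.5)[0]
        expected = hits[-1] + 1 if hits.size else 0
        assert v.selected_m == expected
        np.testing.assert_array_equal(
            v.selected_variables, v.order[: v.selected_m]
        )

    def test_pc2_rejected_for_curves(self):
        X, coding = small_problem()
        with pytest.raises(ValueError):
            vasca_test(X, coding, "A", "pc2_ssq", PermutationPlan(10, seed=0))


class TestUnivariateAndFdr:
    def test_per_variable_null_resolution(self):
        perm = np.zeros((9, 3))
        obs = np.array([1.0, 0.0, -1.0])
        p = univariate_pvalues(perm, obs, pooled=False)
        assert p[0] == pytest.approx(1 / 10)  # above all draws
        assert p[1] == pytest.approx(1.0)  # ties count
        assert p[2] == pytest.approx(1.0)

    def test_pooled_null_resolution(self):
        perm = np.arange(12.0).reshape(4, 3)
        obs = np.array([100.0, -1.0, 6.0])
        p = univariate_pvalues(perm, obs, pooled=True)
        assert p[0] == pytest.approx(1 / 13)
        assert p[1] == pytest.approx(1.0)
        assert p[2] == pytest.approx((6 + 1) / 13)  # draws 6..11 tie or exceed

    def test_fdr_shares_permutation_draws_with_asca(self):
        X, coding = small_problem(n_vars=5)
        plan = PermutationPlan(50, seed=6)
        stats = permuted_column_ssq(X, coding, "A", plan)
        f1 = fdr_test(X, coding, "A", "f_ratio", alpha=0.1, stats=stats)
        f2 = fdr_test(X, coding, "A", "f_ratio", plan=PermutationPlan(50, seed=6),
                      alpha=0.1)
        np.testing.assert_array_equal(f1.p_raw, f2.p_raw)
        assert np.all(f1.p_adjusted >= f1.p_raw)
        assert np.all(f1.p_adjusted <= 1.0)


class TestBhAdjust:
    def test_equal_spaced_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_monotone_pass_from_the_right(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.5, 0.9])), [0.9, 0.9])

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        p=st.lists(
            st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=30
        )
    )
    def test_matches_bruteforce_and_statsmodels(self, p):
        """BH equals both the brute-force step-up definition
        q_i = min_{j: p_j >= p_i (by rank)} p_(j)·M/j and the statsmodels
        implementation."""
        p = np.asarray(p)
        got = bh_adjust(p)
        M = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        brute = np.empty(M)
        for i in range(M):
            brute[i] = min(min(ranked[j] * M / (j + 1) for j in range(i, M)), 1.0)
        expected = np.empty(M)
        expected[order] = brute
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        from statsmodels.stats.multitest import multipletests

        _, sm_adj, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(got, sm_adj, rtol=1e-10)


class TestNullCalibration:
    def test_null_pvalues_on_uniform_grid(self):
        """p-values are never 0 and live on the grid {1,...,K+1}/(K+1)."""
        X, coding = small_problem(n_vars=4)
        plan = PermutationPlan(19, seed=8)
        for kind in ("ssq", "f_ratio"):
            res = asca_test(X, coding, "A", kind, plan)
            assert res.p_value >= 1 / 20
            assert (res.p_value * 20) == pytest.approx(round(res.p_value * 20))

    def test_nested_plans_move_p_by_at_most_one_step(self):
        """Adding one permutation to a nested plan changes the exceedance
        count by at most one, so p moves by at most the grid resolution."""
        X, coding = small_problem(n_vars=4)
        rng = np.random.default_rng(0)
        perms = np.stack([rng.permutation(X.shape[0]) for _ in range(30)])
        p_prev = None
        for K in (10, 20, 30):
            plan = PermutationPlan(K, permutations=perms[:K])
            p = asca_test(X, coding, "A", "f_ratio", plan).p_value
            if p_prev is not None:
                count_prev = p_prev * (K - 10 + 1) - 1
                count = p * (K + 1) - 1
                assert 0 <= count - count_prev <= 10
            p_prev = p
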