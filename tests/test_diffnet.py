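"""Split-based two-sample network test: splitting, screening, statistic,
null distribution, aggregation, baselines and pairwise testing."""

import numpy as np
import pytest
from scipy import stats

from ggmhet.diffnet import (
    aggregate_pvalues,
    diffnet_multi_split,
    diffnet_single_split,
    diffnet_statistic,
    fisherz_test,
    lrt_asym,
    lrt_perm,
    null_pvalue,
    null_weights,
    pairwise_group_tests,
    screen_active_sets,
    split_data,
)
from ggmhet.ggm_core import DataMatrix, active_set_of
from ggmhet.simulate import make_sparse_precision, two_group_scenario


def draw_from_precision(omega, n, rng):
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky((sigma + sigma.T) / 2.0)
    return rng.standard_normal((n, omega.shape[0])) @ chol.T


class TestSplitData:
    def test_even_split_sizes(self, rng):
        X1 = rng.standard_normal((100, 4))
        X2 = rng.standard_normal((100, 4))
        plan = split_data(X1, X2, seed=3)
        for half in (plan.first_half, plan.second_half):
            assert len(half[0]) == 50 and len(half[1]) == 50

    def test_odd_group_sizes_differ_by_one(self, rng):
        plan = split_data(rng.standard_normal((7, 3)),
                          rng.standard_normal((9, 3)), seed=0)
        assert {len(plan.first_half[0]), len(plan.second_half[0])} == {3, 4}
        assert {len(plan.first_half[1]), len(plan.second_half[1])} == {4, 5}

    def test_halves_partition_each_group(self, rng):
        plan = split_data(rng.standard_normal((31, 3)),
                          rng.standard_normal((20, 3)), seed=1)
        for g, n in ((0, 31), (1, 20)):
            combined = np.sort(np.concatenate([plan.first_half[g],
                                               plan.second_half[g]]))
            np.testing.assert_array_equal(combined, np.arange(n))

    def test_deterministic_given_seed(self, rng):
        X1, X2 = rng.standard_normal((20, 3)), rng.standard_normal((20, 3))
        a, b = split_data(X1, X2, seed=11), split_data(X1, X2, seed=11)
        np.testing.assert_array_equal(a.first_half[0], b.first_half[0])
        np.testing.assert_array_equal(a.second_half[1], b.second_half[1])

    def test_too_small_group_errors(self, rng):
        with pytest.raises(ValueError, match=">= 4"):
            split_data(rng.standard_normal((3, 3)),
                       rng.standard_normal((10, 3)), seed=0)


class TestScreenActiveSets:
    def test_diagonal_truth_gives_empty_sets(self, rng):
        X1 = rng.standard_normal((250, 8))
        X2 = rng.standard_normal((250, 8))
        A1, A2, A0 = screen_active_sets(X1, X2)
        assert len(A1) <= 2 and len(A2) <= 2 and len(A0) <= 2

    def test_identical_data_identical_sets(self, rng):
        X = rng.standard_normal((200, 6))
        A1, A2, _ = screen_active_sets(X, X)
        assert A1 == A2

    def test_planted_edge_recovered_in_one_group_only(self, rng):
        """A strong edge (partial correlation 0.6) present in group 1 only
        should enter A1 but stay out of A2 in nearly all replicates."""
        omega = np.eye(4)
        omega[0, 1] = omega[1, 0] = -0.6
        hits = 0
        for r in range(20):
            X1 = draw_from_precision(omega, 500, rng)
            X2 = rng.standard_normal((500, 4))
            A1, A2, _ = screen_active_sets(X1, X2)
            hits += (0, 1) in A1 and (0, 1) not in A2
        assert hits >= 19


class TestDiffnetStatistic:
    def test_identical_data_equal_sets_near_zero(self, rng):
        X = rng.standard_normal((200, 5))
        A = frozenset([(0, 1), (2, 3)])
        stat, _ = diffnet_statistic(X, X, A, A, A)
        assert abs(stat) < 1e-6

    def test_symmetric_in_group_order(self, rng):
        X1, X2 = two_group_scenario(p=6, n_per_group=100, seed=4)
        A1 = frozenset([(0, 1)])
        A2 = frozenset([(1, 2)])
        A0 = frozenset([(0, 1), (1, 2)])
        s12, _ = diffnet_statistic(X1, X2, A1, A2, A0)
        s21, _ = diffnet_statistic(X2, X1, A2, A1, A0)
        assert s12 == pytest.approx(s21, rel=1e-9)

    def test_invariant_to_consistent_variable_reordering(self, rng):
        X1, X2 = two_group_scenario(p=5, n_per_group=120, seed=5)
        perm = np.array([2, 0, 4, 1, 3])
        inv = {old: new for new, old in enumerate(perm)}

        def remap(A):
            return frozenset(tuple(sorted((inv[a], inv[b]))) for a, b in A)

        A1, A2, A0 = (frozenset([(0, 2), (1, 3)]), frozenset([(0, 2)]),
                      frozenset([(0, 2), (1, 3), (2, 4)]))
        s, _ = diffnet_statistic(X1, X2, A1, A2, A0)
        s_perm, _ = diffnet_statistic(X1[:, perm], X2[:, perm],
                                      remap(A1), remap(A2), remap(A0))
        assert s == pytest.approx(s_perm, rel=1e-8)

    def test_matches_independent_reassembly(self, rng):
        """p=2 statistic vs assembling the three restricted fits with a
        generic optimizer on the exactly standardized halves."""
        from scipy.optimize import minimize

        X1, X2 = two_group_scenario(p=2, n_per_group=80, seed=6)
        A = frozenset([(0, 1)])
        stat, _ = diffnet_statistic(X1, X2, A, A, A)

        def standardize_exact(X):
            Xc = X - X.mean(axis=0)
            return Xc / np.sqrt((Xc ** 2).mean(axis=0))

        def fit_ll(S, n):
            def neg(theta):
                a, b, c = theta
                if a <= 0 or c <= 0 or a * c - b * b <= 0:
                    return np.inf
                return -(np.log(a * c - b * b)
                         - (S[0, 0] * a + S[1, 1] * c + 2 * S[0, 1] * b))

            res = minimize(neg, [1, 0, 1], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14})
            return 0.5 * n * (-res.fun - 2 * np.log(2 * np.pi))

        Z1, Z2 = standardize_exact(X1), standardize_exact(X2)
        n1, n2 = len(Z1), len(Z2)
        S1, S2 = Z1.T @ Z1 / n1, Z2.T @ Z2 / n2
        S0 = (n1 * S1 + n2 * S2) / (n1 + n2)
        expected = 2 * (fit_ll(S1, n1) + fit_ll(S2, n2) - fit_ll(S0, n1 + n2))
        assert stat == pytest.approx(expected, abs=1e-6)


class TestNullPvalue:
    def _fits(self, rng, p=5, n=300, seed=0):
        omega = make_sparse_precision(p, 0.3, (0.3, 0.45), seed=seed)
        A = active_set_of(omega)
        X1 = draw_from_precision(omega, n, rng)
        X2 = draw_from_precision(omega, n, rng)
        return diffnet_statistic(X1, X2, A, A, A)

    def test_zero_statistic_gives_pvalue_near_one(self, rng):
        _, fits = self._fits(rng)
        p_asym, _ = null_pvalue(0.0, fits, "asymptotic")
        assert p_asym >= 0.99
        p_boot, _ = null_pvalue(0.0, fits, "bootstrap", n_draws=200)
        assert p_boot >= 0.99

    def test_unit_weights_match_chisquare(self):
        """With unit weights the Monte Carlo mixture reproduces the
        chi-square survival function."""
        from ggmhet.diffnet import _chi2_draw_matrix

        d = 7
        draws = _chi2_draw_matrix(d, 100_000) @ np.ones(d, dtype=np.float32)
        for q in (5.0, 10.0, 16.0):
            mc = np.mean(draws >= q)
            assert mc == pytest.approx(stats.chi2.sf(q, d), abs=0.01)

    def test_full_active_sets_reduce_to_correlation_df(self, rng):
        """Saturated patterns: the weights carry the off-diagonal degrees of
        freedom p(p-1)/2 once per group-difference direction."""
        p, n = 4, 500
        full = frozenset((i, j) for i in range(p) for j in range(i + 1, p))
        X1 = rng.standard_normal((n, p))
        X2 = rng.standard_normal((n, p))
        _, fits = diffnet_statistic(X1, X2, full, full, full)
        w = null_weights(fits)
        assert len(w) == p * (p - 1) // 2
        np.testing.assert_allclose(w, 1.0, atol=0.05)

    def test_asymptotic_agrees_with_bootstrap(self, rng):
        """The weighted chi-square path must track the parametric bootstrap
        within Monte Carlo error on moderate-n fixtures."""
        for seed in range(3):
            stat, fits = self._fits(rng, seed=seed)
            p_asym, _ = null_pvalue(stat, fits, "asymptotic")
            p_boot, _ = null_pvalue(stat, fits, "bootstrap", n_draws=400,
                                    seed=seed)
            assert p_asym == pytest.approx(p_boot, abs=0.10)


class TestAggregatePvalues:
    def test_all_ones_aggregate_to_one(self):
        assert aggregate_pvalues(np.ones(50)) == 1.0

    def test_never_anticonservative_vs_common_value(self):
        for c in (0.001, 0.01, 0.2, 0.7):
            assert aggregate_pvalues(np.full(50, c)) >= c

    def test_matches_dense_grid_oracle(self):
        pvals = np.full(50, 0.01)
        gmin = 0.05
        gammas = np.linspace(gmin, 1.0, 20000)
        q = np.quantile(pvals, gammas)
        oracle = min(1.0, (1 - np.log(gmin)) * np.min(np.minimum(1.0, q / gammas)))
        assert aggregate_pvalues(pvals, gmin) == pytest.approx(oracle, rel=1e-6)

    def test_rejects_empty_and_invalid(self):
        with pytest.raises(ValueError):
            aggregate_pvalues([])
        with pytest.raises(ValueError):
            aggregate_pvalues([0.5, 1.2])


class TestSingleAndMultiSplit:
    def test_fixed_seed_reproducible(self):
        X1, X2 = two_group_scenario(p=6, n_per_group=120, seed=8)
        r1 = diffnet_single_split(X1, X2, seed=42)
        r2 = diffnet_single_split(X1, X2, seed=42)
        assert r1.statistic == r2.statistic and r1.pvalue == r2.pvalue

    def test_single_split_power_on_strong_alternative(self):
        rejections = 0
        for s in range(10):
            X1, X2 = two_group_scenario(p=10, n_per_group=500,
                                        n_edges_changed=10, seed=100 + s)
            rejections += diffnet_single_split(X1, X2, seed=s).pvalue <= 0.05
        assert rejections >= 9

    def test_multi_split_single_split_relationship(self):
        """With one split, aggregation can only inflate the single-split
        P-value (by at most the 1 - log(gamma_min) factor)."""
        X1, X2 = two_group_scenario(p=6, n_per_group=150, seed=9)
        ms = diffnet_multi_split(X1, X2, n_splits=1, seed=5)
        inner_seed = int(np.random.default_rng(5).integers(0, 2**31 - 1, size=1)[0])
        ss = diffnet_single_split(X1, X2, seed=inner_seed)
        assert ms.pvalue >= min(1.0, ss.pvalue)
        assert ms.pvalue <= min(1.0, (1 - np.log(0.05)) * ss.pvalue) + 1e-12

    def test_multi_split_result_contract(self):
        X1, X2 = two_group_scenario(p=6, n_per_group=120, seed=10)
        res = diffnet_multi_split(X1, X2, n_splits=5, seed=1)
        assert res.n_splits == 5
        assert len(res.per_split_pvalues) == 5
        assert np.all((res.per_split_pvalues >= 0) & (res.per_split_pvalues <= 1))
        assert 0 <= res.pvalue <= 1


class TestNullUniformity:
    def test_single_split_null_pvalues_uniform(self, ss_null_pvalues):
        """Under H0 the single-split P-values are uniform on [0, 1]
        (Kolmogorov-Smirnov at the 1% level)."""
        res = stats.kstest(ss_null_pvalues, "uniform")
        assert res.pvalue > 0.01, res


class TestBaselines:
    def test_lrt_identical_groups_pvalue_near_one(self, rng):
        X = rng.standard_normal((100, 4))
        assert lrt_asym(X, X.copy()) > 0.99

    def test_lrt_p1_matches_variance_ratio_lrt(self, rng):
        """p=1 reduces to the classical two-sample variance LRT; check the
        statistic against its closed form (chi-square with 1 df)."""
        x1 = rng.normal(0, 1.0, size=(200, 1))
        x2 = rng.normal(0, 1.3, size=(150, 1))
        # closed form: (n1+n2) log s0 - n1 log s1 - n2 log s2, mean-centered
        v1 = x1.var()
        v2 = x2.var()
        v0 = (200 * v1 + 150 * v2) / 350
        stat = 350 * np.log(v0) - 200 * np.log(v1) - 150 * np.log(v2)
        expected = stats.chi2.sf(stat, 1)
        # lrt_asym requires p >= 2 shapes via DataMatrix; call internals
        from ggmhet.diffnet import _lrt_statistic

        assert _lrt_statistic(x1, x2) == pytest.approx(stat, rel=1e-10)
        assert stats.chi2.sf(_lrt_statistic(x1, x2), 1) == pytest.approx(expected)

    def test_lrt_asym_oversizes_when_p_near_n(self, rng):
        """The classical asymptotic LRT fails to control type-I error when
        the number of covariance parameters approaches n."""
        rejections = 0
        for s in range(20):
            rng_s = np.random.default_rng(s)
            X1 = rng_s.standard_normal((100, 60))
            X2 = rng_s.standard_normal((100, 60))
            rejections += lrt_asym(X1, X2) <= 0.05
        assert rejections == 20

    def test_lrt_perm_minimum_pvalue_and_reproducibility(self, rng):
        X1 = rng.standard_normal((40, 3))
        X2 = rng.standard_normal((40, 3)) * 3.0
        p1 = lrt_perm(X1, X2, n_perm=99, seed=7)
        p2 = lrt_perm(X1, X2, n_perm=99, seed=7)
        assert p1 == p2
        assert p1 >= 1.0 / 100.0

    def test_fisherz_p2_reduces_to_single_pair_z_test(self, rng):
        """With p=2 there is one partial correlation (= the correlation) and
        no multiplicity correction."""
        X1 = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=200)
        X2 = rng.multivariate_normal([0, 0], [[1, 0.1], [0.1, 1]], size=200)
        p = fisherz_test(X1, X2)
        from ggmhet.ggm_core import sample_covariance, partial_correlations

        r1 = partial_correlations(np.linalg.inv(sample_covariance(X1)))[0, 1]
        r2 = partial_correlations(np.linalg.inv(sample_covariance(X2)))[0, 1]
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / 197 + 1 / 197)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_fisherz_detects_single_strong_edge(self, rng):
        hits = 0
        for s in range(10):
            rng_s = np.random.default_rng(300 + s)
            omega = np.eye(6)
            omega[0, 1] = omega[1, 0] = -0.5
            X1 = draw_from_precision(omega, 500, rng_s)
            X2 = rng_s.standard_normal((500, 6))
            hits += fisherz_test(X1, X2) < 0.01
        assert hits >= 9

    def test_sample_size_preconditions(self, rng):
        small = rng.standard_normal((6, 6))
        with pytest.raises(ValueError):
            lrt_asym(small, small.copy() * 2)
        with pytest.raises(ValueError):
            fisherz_test(small, small.copy() * 2)


class TestPairwiseGroupTests:
    def test_symmetric_output_and_mask(self, rng):
        X = np.vstack([rng.standard_normal((60, 4)),
                       rng.standard_normal((60, 4)),
                       rng.standard_normal((60, 4))])
        groups = np.repeat(["a", "b", "c"], 60)
        data = DataMatrix(X, [f"V{j}" for j in range(4)], groups)
        P, mask = pairwise_group_tests(data, method="lrt-asym")
        np.testing.assert_allclose(P.values, P.values.T, equal_nan=True)
        assert mask.equals(mask.T)

    def test_two_groups_single_unadjusted_pvalue(self, rng):
        X = np.vstack([rng.standard_normal((50, 4)),
                       rng.standard_normal((50, 4))])
        groups = np.repeat(["g1", "g2"], 50)
        data = DataMatrix(X, [f"V{j}" for j in range(4)], groups)
        P, _ = pairwise_group_tests(data, method="lrt-asym")
        from ggmhet.ggm_core import standardize_by_group

        Z = standardize_by_group(data, groups)
        raw = lrt_asym(Z.values[:50], Z.values[50:])
        assert P.loc["g1", "g2"] == pytest.approx(raw, rel=1e-10)

    def test_null_groups_rarely_significant(self, rng):
        X = np.vstack([rng.standard_normal((80, 4)) for _ in range(3)])
        groups = np.repeat(["a", "b", "c"], 80)
        data = DataMatrix(X, [f"V{j}" for j in range(4)], groups)
        _, mask = pairwise_group_tests(data, method="lrt-perm", seed=3,
                                       n_perm=99)
        assert mask.values.sum() == 0
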