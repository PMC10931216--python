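import numpy as np
import pytest

from pedclim.rcca import (
    canonical_scores,
    fit_rcca,
    multivariate_tests,
    pearson_matrix,
    permutation_test,
    redundancy,
    standardize,
    variance_shares,
)
from pedclim.simulate import simulate_linked_blocks

from conftest import classical_cca_correlations

TABLE_R = np.array([0.339, 0.166, 0.071, 0.057, 0.048, 0.039])


@pytest.fixture(scope="module")
def planted():
    X, Y, truth = simulate_linked_blocks(2000, 5, 7, rho=0.6, seed=3)
    Zx, *_ = standardize(X)
    Zy, *_ = standardize(Y)
    return Zx, Zy


class TestStandardize:
    def test_three_point_column(self):
        Z, m, s = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert Z[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
        assert m[0] == 2.0 and s[0] == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        Z1, *_ = standardize(rng.normal(size=(100, 3)))
        Z2, *_ = standardize(Z1)
        assert np.allclose(Z1, Z2, atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(1)
        Z, *_ = standardize(rng.normal(2.0, 5.0, size=(500, 4)))
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="1"):
            standardize(np.c_[np.arange(5.0), np.ones(5)])


class TestPearson:
    def test_self_correlation_one(self):
        x = np.arange(10.0).reshape(-1, 1)
        Rxx, Ryy, Rxy = pearson_matrix(x, x.copy())
        assert Rxy[0, 0] == pytest.approx(1.0)

    def test_antimonotone_pair(self):
        x = np.random.default_rng(2).normal(size=(50, 1))
        _, _, Rxy = pearson_matrix(x, -x)
        assert Rxy[0, 0] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        Rxx, Ryy, Rxy = pearson_matrix(
            rng.normal(size=(10_000, 3)), rng.normal(size=(10_000, 4))
        )
        assert np.all(np.abs(Rxy) < 0.05)
        assert np.allclose(np.diag(Rxx), 1.0)
        assert np.allclose(Rxx, Rxx.T)


class TestFit:
    def test_one_dimensional_reduction_to_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 1))
        y = 0.5 * x + rng.normal(size=(200, 1))
        Zx, *_ = standardize(x)
        Zy, *_ = standardize(y)
        r_expected = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert fit_rcca(Zx, Zy).r[0] == pytest.approx(r_expected, abs=1e-12)

    def test_identical_sets_perfect_correlation(self):
        rng = np.random.default_rng(5)
        Z, *_ = standardize(rng.normal(size=(100, 3)))
        assert fit_rcca(Z, Z.copy()).r == pytest.approx(np.ones(3), abs=1e-8)

    def test_planted_correlation_recovered(self, planted):
        fit = fit_rcca(*planted)
        assert 0.55 <= fit.r[0] <= 0.65
        assert fit.r[1] < 0.12

    def test_matches_classical_cca_oracle(self):
        rng = np.random.default_rng(6)
        for seed in (0, 1, 2):
            X, Y, _ = simulate_linked_blocks(400, 4, 6, rho=0.5, seed=seed)
            Zx, *_ = standardize(X)
            Zy, *_ = standardize(Y)
            fit = fit_rcca(Zx, Zy)
            assert np.allclose(fit.r, classical_cca_correlations(X, Y), atol=1e-8)

    def test_ridge_shrinks_first_correlation(self, planted):
        Zx, Zy = planted
        r_prev = np.inf
        for lam in (0.0, 0.01, 0.1, 1.0, 10.0):
            r1 = fit_rcca(Zx, Zy, lambda1=lam).r[0]
            assert r1 <= r_prev + 1e-12
            r_prev = r1

    def test_sign_convention_deterministic(self, planted):
        fit = fit_rcca(*planted)
        for i in range(fit.r.size):
            j = np.argmax(np.abs(fit.loadings_X[:, i]))
            assert fit.loadings_X[j, i] > 0

    def test_rejects_bad_input(self, planted):
        Zx, Zy = planted
        with pytest.raises(ValueError):
            fit_rcca(Zx, Zy, lambda1=-0.1)
        bad = Zx.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_rcca(bad, Zy)

    def test_meaningful_flag_threshold(self, planted):
        fit = fit_rcca(*planted)
        assert fit.meaningful.tolist() == (fit.r >= 0.30).tolist()


class TestVarianceShares:
    def test_single_nonzero(self):
        assert variance_shares(np.array([2.5, 0.0]))[0] == 100.0

    def test_equal_eigenvalues(self):
        assert variance_shares(np.ones(4)) == pytest.approx([25.0] * 4)

    def test_printed_correlations_first_share(self):
        ev = TABLE_R**2 / (1 - TABLE_R**2)
        assert variance_shares(ev)[0] == pytest.approx(76.28, abs=0.15)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            variance_shares(np.zeros(3))


class TestRedundancy:
    def test_single_variable_sets_reduce_to_r2(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(300, 1))
        y = 0.6 * x + rng.normal(size=(300, 1))
        Zx, *_ = standardize(x)
        Zy, *_ = standardize(y)
        fit = fit_rcca(Zx, Zy)
        rd = redundancy(fit)
        assert rd["X"][0] == pytest.approx(fit.r2[0], abs=1e-10)
        assert rd["Y"][0] == pytest.approx(fit.r2[0], abs=1e-10)

    def test_independent_sets_near_zero(self):
        rng = np.random.default_rng(8)
        Zx, *_ = standardize(rng.normal(size=(4000, 3)))
        Zy, *_ = standardize(rng.normal(size=(4000, 3)))
        rd = redundancy(fit_rcca(Zx, Zy))
        assert rd["X_total"] < 0.02 and rd["Y_total"] < 0.02

    def test_totals_are_sums(self, planted):
        rd = redundancy(fit_rcca(*planted))
        assert rd["X_total"] == pytest.approx(rd["X"].sum())
        assert rd["Y_total"] == pytest.approx(rd["Y"].sum())


class TestMultivariate:
    def test_null_correlations(self):
        sig = multivariate_tests(np.zeros(3), 100, 3, 5)
        assert sig.pillai == 0.0 and sig.hotelling == 0.0
        assert sig.wilks == 1.0 and sig.roy == 0.0

    def test_hypothesis_df_is_pq(self):
        sig = multivariate_tests(TABLE_R, 10_823, 6, 9)
        assert sig.df_hyp["pillai"] == 54 == 6 * 9

    def test_internal_consistency_with_returned_r(self, planted):
        fit = fit_rcca(*planted)
        sig = multivariate_tests(fit.r, fit.n, 5, 7)
        assert sig.wilks == pytest.approx(np.prod(1 - fit.r2), abs=1e-12)
        assert sig.pillai == pytest.approx(fit.r2.sum(), abs=1e-12)
        assert sig.hotelling == pytest.approx(fit.eigenvalues.sum(), abs=1e-12)
        assert sig.roy == pytest.approx(fit.r2[0], abs=1e-12)
        assert sig.roots_table[0]["wilks"] == pytest.approx(sig.wilks)

    def test_root_sequence_dfs(self):
        sig = multivariate_tests(TABLE_R, 10_823, 6, 9)
        assert [row["df_hyp"] for row in sig.roots_table] == [54, 40, 28, 18, 10, 4]
        assert sig.roots_table[-1]["df_err"] == pytest.approx(10_813)

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            multivariate_tests(np.zeros(2), 8, 3, 5)


class TestPermutation:
    def test_pvalues_within_estimator_bounds(self, planted):
        p = permutation_test(*planted, B=99, seed=0)
        assert np.all(p >= 1.0 / 100.0) and np.all(p <= 1.0)

    def test_planted_signal_maximally_significant(self):
        X, Y, _ = simulate_linked_blocks(500, 4, 4, rho=0.6, seed=9)
        Zx, *_ = standardize(X)
        Zy, *_ = standardize(Y)
        p = permutation_test(Zx, Zy, B=999, seed=1)
        assert p[0] == pytest.approx(1.0 / 1000.0)

    def test_seed_reproducible(self, planted):
        p1 = permutation_test(*planted, B=99, seed=7)
        p2 = permutation_test(*planted, B=99, seed=7)
        assert np.array_equal(p1, p2)


class TestScores:
    def test_training_scores_reproduce_r(self, planted):
        fit = fit_rcca(*planted)
        sx, sy = canonical_scores(fit, *planted)
        r1 = np.corrcoef(sx[:, 0], sy[:, 0])[0, 1]
        assert r1 == pytest.approx(fit.r[0], abs=1e-10)

    def test_zero_input_zero_scores(self, planted):
        fit = fit_rcca(*planted)
        sx, sy = canonical_scores(fit, np.zeros((5, 5)), np.zeros((5, 7)))
        assert not sx.any() and not sy.any()

    def test_held_out_half_recovers_signal(self):
        X, Y, _ = simulate_linked_blocks(2000, 5, 7, rho=0.6, seed=10)
        Zx, *_ = standardize(X)
        Zy, *_ = standardize(Y)
        fit = fit_rcca(Zx[:1000], Zy[:1000])
        sx, sy = canonical_scores(fit, Zx[1000:], Zy[1000:])
        r = abs(np.corrcoef(sx[:, 0], sy[:, 0])[0, 1])
        assert 0.5 <= r <= 0.7

    def test_dimension_mismatch_errors(self, planted):
        fit = fit_rcca(*planted)
        with pytest.raises(ValueError):
            canonical_scores(fit, np.zeros((5, 4)), np.zeros((5, 7)))
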