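import numpy as np
import pytest
from scipy import stats

from astwas.association import (
    DegenerateKernelError,
    ZScores,
    astwas_test,
    fit_null_model,
    ld_matrix,
    linear_twas_test,
    mixture_chisq_pvalue,
    q_statistic,
)
from astwas.kernels import KernelMatrix, KernelSpec
from astwas.pvalues import liu_tail, mixture_tail


def _kernel(M):
    return KernelMatrix(np.asarray(M, dtype=float), KernelSpec("linear", "none"), snp_count=1)


class TestNullModel:
    def test_quantitative_hand_values(self):
        null = fit_null_model(np.array([0.0, 2.0, 4.0]))
        np.testing.assert_allclose(null.fitted_mean, 2.0)
        assert null.variance_scale == pytest.approx(4.0)  # n-1 denominator

    def test_binary_prevalence(self):
        null = fit_null_model(np.array([0.0, 1.0, 1.0, 1.0]), "binary")
        np.testing.assert_allclose(null.fitted_mean, 0.75)
        assert null.variance_scale == pytest.approx(0.75 * 0.25)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_null_model(np.ones(5))
        with pytest.raises(ValueError, match="single class"):
            fit_null_model(np.ones(5), "binary")
        with pytest.raises(ValueError, match="0/1"):
            fit_null_model(np.array([0.0, 0.5, 1.0]), "binary")


class TestQStatistic:
    def test_identity_kernel_zero_mean(self):
        null = fit_null_model(np.array([1.0, 2.0, 3.0]))
        null.fitted_mean = np.zeros(2)
        q = q_statistic(np.array([1.0, 2.0]), _kernel(np.eye(2)), null)
        assert q == pytest.approx(5.0)

    def test_zero_residual(self):
        y = np.array([1.0, 2.0, 3.0])
        null = fit_null_model(y)
        null.fitted_mean = y.copy()
        assert q_statistic(y, _kernel(np.eye(3)), null) == pytest.approx(0.0)

    def test_hand_quadratic_form(self):
        null = fit_null_model(np.array([9.0, 1.0, 5.0]))
        null.fitted_mean = np.zeros(2)
        q = q_statistic(np.array([1.0, -1.0]), _kernel([[2.0, 1.0], [1.0, 2.0]]), null)
        assert q == pytest.approx(2.0)

    def test_invariant_under_joint_permutation(self, rng, small_genotypes):
        y = rng.standard_normal(300)
        w = rng.standard_normal(20)
        q0 = astwas_test(small_genotypes.dosages, w, y).statistic_q
        perm = rng.permutation(300)
        q1 = astwas_test(small_genotypes.dosages[perm], w, y[perm]).statistic_q
        assert q0 == pytest.approx(q1, rel=1e-10)


class TestMixturePValue:
    def test_single_chi2_tail(self):
        p, method = mixture_tail(3.841, np.array([1.0]))
        assert p == pytest.approx(stats.chi2.sf(3.841, 1), rel=1e-9)
        assert method == "davies"

    def test_q_zero_all_positive(self):
        p, _ = mixture_tail(0.0, np.array([0.5, 1.0, 2.0]))
        assert p == pytest.approx(1.0)

    def test_matches_exact_chi2_k(self):
        # sum of k unit-weight chi2_1 is chi2_k: closed-form oracle
        for k, q in [(2, 5.99), (5, 11.07), (10, 3.0)]:
            p, method = mixture_tail(q, np.ones(k))
            assert method == "davies"
            assert p == pytest.approx(stats.chi2.sf(q, k), rel=1e-8)

    def test_liu_fallback_close_to_exact(self):
        lam = np.array([1.0, 0.5, 0.25])
        for q in [0.5, 2.0, 6.0]:
            exact, _ = mixture_tail(q, lam)
            assert liu_tail(q, lam) == pytest.approx(exact, abs=0.02)

    def test_degenerate_kernel(self):
        null = fit_null_model(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateKernelError):
            mixture_chisq_pvalue(0.0, _kernel(np.ones((3, 3))), null)
        # rank-deficient but not degenerate: constant kernel is removed by centering

    def test_permutation_oracle_small_instance(self, rng):
        n, p = 50, 5
        G = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        w = rng.standard_normal(p)
        y = rng.standard_normal(n)
        res = astwas_test(G, w, y)
        null = fit_null_model(y)
        K = (G * w) @ G.T
        r = y - null.fitted_mean
        B = 10_000
        perms = np.array([rng.permutation(r) for _ in range(B)])
        qs = np.einsum("bi,ij,bj->b", perms, K, perms)
        q_obs = r @ K @ r
        # orient the permutation tail the same way as the analytic test
        p_perm = np.mean(qs >= q_obs)
        Kc = K - K.mean(0) - K.mean(1)[:, None] + K.mean()
        if np.linalg.eigvalsh((Kc + Kc.T) / 2).sum() < 0:
            p_perm = np.mean(qs <= q_obs)
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p_value - p_perm) <= 3 * max(se, 1e-4)


class TestAstwasTest:
    def test_all_zero_weights_give_p_one(self, rng, small_genotypes):
        y = rng.standard_normal(300)
        with pytest.warns(RuntimeWarning, match="all-zero"):
            res = astwas_test(small_genotypes, np.zeros(20), y)
        assert res.p_value == 1.0

    def test_single_snp_reduces_to_score_test(self, rng):
        n = 120
        for sign in (1.0, -1.0):
            x = rng.binomial(2, 0.35, n).astype(float)
            y = rng.standard_normal(n) + 0.25 * x
            w = sign * abs(rng.standard_normal()) * 0.7
            res = astwas_test(x[:, None], np.array([w]), y)
            xc, r = x - x.mean(), y - y.mean()
            z2 = (xc @ r) ** 2 / (np.var(y, ddof=1) * (xc @ xc))
            assert res.p_value == pytest.approx(stats.chi2.sf(z2, 1), rel=1e-6)

    def test_full_kernel_path_agrees_with_fast_path(self, rng):
        # the n x n eigendecomposition and the p x p reduction are dual routes
        G = rng.binomial(2, 0.3, size=(40, 6)).astype(float)
        w = rng.standard_normal(6)
        y = rng.standard_normal(40)
        fast = astwas_test(G, w, y)
        null = fit_null_model(y)
        K = _kernel((G * w) @ G.T)
        q = q_statistic(y, K, null)
        slow_p, _ = mixture_chisq_pvalue(q, K, null)
        assert fast.statistic_q == pytest.approx(q, rel=1e-10)
        assert fast.p_value == pytest.approx(slow_p, rel=1e-6)

    def test_binary_trait_runs_and_is_valid(self, rng, small_genotypes):
        y = (rng.random(300) < 0.4).astype(float)
        w = rng.standard_normal(20)
        res = astwas_test(small_genotypes, w, y, trait_type="binary")
        assert 0.0 <= res.p_value <= 1.0


class TestLinearBaseline:
    def test_single_snp_identity(self):
        res = linear_twas_test(np.array([1.0]), ZScores(["a"], np.array([2.5]), np.eye(1)))
        assert res.statistic_q == pytest.approx(2.5)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(2.5))

    def test_perfectly_correlated_pair(self):
        ld = np.array([[1.0, 1.0], [1.0, 1.0]])
        res = linear_twas_test(
            np.array([0.7, 0.7]), ZScores(["a", "b"], np.array([1.8, 1.8]), ld)
        )
        assert res.statistic_q == pytest.approx(1.8)

    def test_orthogonal_weights_give_p_one(self):
        res = linear_twas_test(
            np.array([1.0, -1.0]), ZScores(["a", "b"], np.array([1.3, 1.3]), np.eye(2))
        )
        assert res.statistic_q == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            linear_twas_test(np.zeros(2), ZScores(["a", "b"], np.ones(2), np.eye(2)))


class TestLdMatrix:
    def test_duplicate_and_anticoded_columns(self, rng):
        x = rng.binomial(2, 0.4, 30).astype(float)
        G = np.column_stack([x, x, 2.0 - x])
        R = ld_matrix(G)
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_independent_columns_near_zero(self, rng):
        G = rng.binomial(2, 0.3, size=(10_000, 4)).astype(float)
        R = ld_matrix(G)
        off = R[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_constant_column_names_snp(self, small_genotypes):
        gm = small_genotypes.take_variants(np.arange(3))
        gm.dosages[:, 1] = 1.0
        with pytest.raises(ValueError, match="snp1"):
            ld_matrix(gm)
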