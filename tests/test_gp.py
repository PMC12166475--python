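import math

import numpy as np
import pytest
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform
from scipy.stats import multivariate_normal

from spotweight import (
    KernelParams,
    exp_kernel,
    fit_gene_gp,
    fit_genes,
    gp_loglik_exact,
    gp_loglik_nn,
    make_hexgrid,
    morans_i,
    rank_genes,
)
from spotweight.gp import NNStructure, fitted_values, linear_loglik


def mvn_gls_oracle(y, X, Sigma):
    """Independent likelihood oracle: explicit inverse + GLS + scipy MVN pdf."""
    Si = np.linalg.inv(Sigma)
    beta = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
    return multivariate_normal(mean=X @ beta, cov=Sigma).logpdf(y), beta


class TestExpKernel:
    def test_zero_distance(self):
        p = KernelParams(2.5, 0.0, 1.0)
        C = exp_kernel(np.zeros((3, 2)), p)
        np.testing.assert_allclose(C, 2.5)

    def test_distance_equals_lengthscale(self):
        p = KernelParams(1.0, 0.0, 2.0)
        coords = np.array([[0.0, 0.0], [2.0, 0.0]])
        C = exp_kernel(coords, p)
        assert abs(C[0, 1] - math.exp(-1)) < 1e-12

    def test_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 5, (12, 2))
        p = KernelParams(1.7, 0.0, 0.8)
        C = exp_kernel(coords, p)
        for i in range(12):
            for j in range(12):
                d = math.dist(coords[i], coords[j])
                assert abs(C[i, j] - 1.7 * math.exp(-d / 0.8)) < 1e-12
        np.testing.assert_allclose(C, C.T)

    def test_bad_lengthscale(self):
        with pytest.raises(ValueError):
            KernelParams(1.0, 1.0, 0.0)


class TestExactLoglik:
    def test_iid_reduction(self, rng):
        # sigma2 = 0, tau2 = 1: iid standard normal around the mean
        y = rng.standard_normal(40)
        X = np.ones((40, 1))
        ll, beta = gp_loglik_exact(y, X, rng.uniform(0, 1, (40, 2)),
                                   KernelParams(0.0, 1.0, 1.0))
        expected = float(np.sum(-0.5 * math.log(2 * math.pi)
                                - 0.5 * (y - y.mean()) ** 2))
        assert abs(ll - expected) < 1e-10
        assert abs(beta[0] - y.mean()) < 1e-10

    def test_mvn_oracle(self, rng):
        coords = np.array([[0, 0], [1, 0], [0, 1], [2, 2], [1.5, 0.5]], float)
        y = np.array([0.3, -1.2, 0.7, 2.0, -0.5])
        X = np.column_stack([np.ones(5), coords[:, 0]])
        p = KernelParams(1.3, 0.4, 0.9)
        Sigma = exp_kernel(coords, p) + 0.4 * np.eye(5)
        ll_oracle, beta_oracle = mvn_gls_oracle(y, X, Sigma)
        ll, beta = gp_loglik_exact(y, X, coords, p)
        assert abs(ll - ll_oracle) < 1e-8
        np.testing.assert_allclose(beta, beta_oracle, atol=1e-8)

    def test_duplicate_spot_with_nugget(self, rng):
        coords = np.array([[0, 0], [0, 0], [1, 1]], float)
        y = np.array([1.0, 2.0, 3.0])
        ll, _ = gp_loglik_exact(y, np.ones((3, 1)), coords,
                                KernelParams(1.0, 0.5, 1.0))
        assert np.isfinite(ll)

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            gp_loglik_exact(np.zeros(3), np.ones((3, 1)), np.zeros((3, 2)),
                            KernelParams(0.0, 0.0, 1.0))

    def test_rank_deficient_X_raises(self, rng):
        y = rng.standard_normal(10)
        X = np.ones((10, 2))  # duplicated column
        with pytest.raises(np.linalg.LinAlgError):
            gp_loglik_exact(y, X, rng.uniform(0, 1, (10, 2)),
                            KernelParams(1.0, 0.5, 1.0))


class TestNNLoglik:
    def test_full_conditioning_equals_exact(self, rng):
        coords = rng.uniform(0, 1, (10, 2))
        y = rng.standard_normal(10)
        X = np.ones((10, 1))
        p = KernelParams(0.8, 0.3, 0.4)
        ll_e, _ = gp_loglik_exact(y, X, coords, p)
        ll_n, _ = gp_loglik_nn(y, X, coords, p, m=9)
        assert abs(ll_e - ll_n) < 1e-8

    @pytest.mark.parametrize("n", [15, 30, 50])
    def test_convergence_with_m(self, rng, n):
        coords = rng.uniform(0, 1, (n, 2))
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        p = KernelParams(1.0, 0.5, 0.3)
        ll_e, _ = gp_loglik_exact(y, X, coords, p)
        ll_full, _ = gp_loglik_nn(y, X, coords, p, m=n - 1)
        assert abs(ll_e - ll_full) < 1e-8

    def test_m15_within_one_percent(self, rng):
        # simulated spatial data, n = 200
        coords = rng.uniform(0, 1, (200, 2))
        p = KernelParams(1.0, 0.3, 0.2)
        Sigma = exp_kernel(coords, p) + 0.3 * np.eye(200)
        y = cholesky(Sigma, lower=True) @ rng.standard_normal(200)
        X = np.ones((200, 1))
        ll_e, _ = gp_loglik_exact(y, X, coords, p)
        ll_n, _ = gp_loglik_nn(y, X, coords, p, m=15)
        assert abs(ll_n - ll_e) / abs(ll_e) < 0.01

    def test_m1_finite(self, rng):
        coords = rng.uniform(0, 1, (20, 2))
        y = rng.standard_normal(20)
        ll, _ = gp_loglik_nn(y, np.ones((20, 1)), coords,
                             KernelParams(1.0, 0.5, 0.3), m=1)
        assert np.isfinite(ll)

    def test_m_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            NNStructure(np.zeros((5, 2)), m=0)


class TestInvariances:
    def test_translation_rotation(self, rng):
        coords = rng.uniform(0, 1, (25, 2))
        y = rng.standard_normal(25)
        X = np.ones((25, 1))
        p = KernelParams(1.0, 0.4, 0.3)
        ll0, _ = gp_loglik_exact(y, X, coords, p)
        th = 0.7
        Rm = np.array([[math.cos(th), -math.sin(th)],
                       [math.sin(th), math.cos(th)]])
        moved = coords @ Rm.T + np.array([5.0, -3.0])
        ll1, _ = gp_loglik_exact(y, X, moved, p)
        assert abs(ll0 - ll1) < 1e-8

    def test_lr_invariant_to_shift(self, rng):
        coords = rng.uniform(0, 100, (40, 2))
        y = rng.standard_normal(40)
        f0 = fit_genes(y[:, None], coords)[0]
        f1 = fit_genes(y[:, None] + 7.5, coords)[0]
        assert abs(f0.lr_stat - f1.lr_stat) < 1e-6


class TestFitGene:
    def test_pure_noise_small_lr(self, rng):
        coords = make_hexgrid(7, 7, 1.0)
        y = rng.standard_normal(49)
        fit = fit_gene_gp(y, None, coords)
        assert fit.lr_stat < 6.0
        assert fit.prop_sv < 0.6

    def test_constant_y_no_crash(self):
        coords = make_hexgrid(5, 5, 1.0)
        fit = fit_gene_gp(np.ones(25), None, coords)
        assert np.isfinite(fit.loglik)
        assert fit.lr_stat >= 0.0

    def test_prop_sv_consistent(self, rng):
        coords = make_hexgrid(6, 6, 1.0)
        y = rng.standard_normal(36)
        fit = fit_gene_gp(y, None, coords)
        p = fit.params
        assert abs(fit.prop_sv - p.sigma2 / (p.sigma2 + p.tau2)) < 1e-12

    def test_matches_batched_fitter(self, rng):
        coords = make_hexgrid(8, 8, 1.0)
        D = squareform(pdist(coords))
        L = cholesky(np.exp(-D / 2.0) + 1e-10 * np.eye(64), lower=True)
        y = L @ rng.standard_normal(64) + 0.5 * rng.standard_normal(64)
        single = fit_gene_gp(y, None, coords)
        batched = fit_genes(y[:, None], coords)[0]
        # two different optimizers maximizing the same objective
        assert abs(single.loglik - batched.loglik) < 0.1
        assert abs(single.lr_stat - batched.lr_stat) < 0.2

    def test_parameter_recovery_median(self, rng):
        coords = make_hexgrid(15, 16, 100.0)
        n = coords.shape[0]
        D = squareform(pdist(coords))
        L = cholesky(np.exp(-D / 100.0) + 1e-10 * np.eye(n), lower=True)
        G = 200
        Y = (math.sqrt(0.5) * (L @ rng.standard_normal((n, G)))
             + math.sqrt(0.5) * rng.standard_normal((n, G)))
        fits = fit_genes(Y, coords)
        med = np.median([f.prop_sv for f in fits])
        assert abs(med - 0.5) < 0.15


class TestRankGenes:
    def test_forced_order(self):
        fits = fit_genes(np.random.default_rng(3).standard_normal((20, 3)),
                         np.random.default_rng(4).uniform(0, 1, (20, 2)))
        fits[0].lr_stat, fits[1].lr_stat, fits[2].lr_stat = 3.0, 1.0, 2.0
        table = rank_genes(fits, ["a", "b", "c"])
        assert table.rank.tolist() == [1, 3, 2]

    def test_ties_first(self):
        fits = fit_genes(np.random.default_rng(3).standard_normal((20, 2)),
                         np.random.default_rng(4).uniform(0, 1, (20, 2)))
        fits[0].lr_stat = fits[1].lr_stat = 2.0
        table = rank_genes(fits, ["a", "b"])
        assert table.rank.tolist() == [1, 2]


class TestMoransI:
    def test_gradient_positive(self):
        coords = make_hexgrid(8, 8, 1.0)
        y = coords[:, 0] + coords[:, 1]
        assert morans_i(y, coords) > 0.2

    def test_permutation_null_mean(self, rng):
        coords = make_hexgrid(6, 6, 1.0)
        y = rng.standard_normal(36)
        vals = []
        for _ in range(300):
            vals.append(morans_i(rng.permutation(y), coords))
        expected = -1.0 / 35
        assert abs(np.mean(vals) - expected) < 4 * np.std(vals) / math.sqrt(300)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(10), np.random.default_rng(0).uniform(0, 1, (10, 2)))


class TestFittedValues:
    def test_null_gene_returns_fixed_effect(self, rng):
        coords = make_hexgrid(6, 6, 1.0)
        y = rng.standard_normal((36, 1))
        fits = fit_genes(y, coords)
        fits[0].params.sigma2 = 0.0
        pred = fitted_values(y, coords, fits)
        np.testing.assert_allclose(pred[:, 0], fits[0].mu_hat)

    def test_matches_dense_kriging_oracle(self, rng):
        # with the neighborhood covering all points, the local smoother must
        # equal the dense kriging formula
        n = 30
        coords = rng.uniform(0, 100, (n, 2))
        y = rng.standard_normal((n, 1))
        fits = fit_genes(y, coords)
        f = fits[0]
        f.params = KernelParams(1.2, 0.7, 40.0)
        f.mu_hat = np.full(n, 0.3)
        pred = fitted_values(y, coords, fits, m=n - 1)[:, 0]
        d = squareform(pdist(coords))
        C = 1.2 * np.exp(-d / 40.0)
        Sigma = C + (0.7 + 1e-10 * 1.2) * np.eye(n)
        oracle = 0.3 + C @ np.linalg.solve(Sigma, y[:, 0] - 0.3)
        np.testing.assert_allclose(pred, oracle, atol=1e-8)


class TestLinearLoglik:
    def test_matches_closed_form(self, rng):
        y = rng.standard_normal(30)
        X = np.ones((30, 1))
        ll, beta = linear_loglik(y, X)
        s2 = np.mean((y - y.mean()) ** 2)
        expected = -0.5 * 30 * (math.log(2 * math.pi) + math.log(s2) + 1.0)
        assert abs(ll - expected) < 1e-10
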