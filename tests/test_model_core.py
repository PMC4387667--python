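"""Oracle checks for the covariance algebra, likelihood and gradients."""

import numpy as np
import pytest
from scipy import stats

import groupeqtl as gq

from conftest import random_instance


class TestCovariance:
    def test_zero_low_rank_parts_give_identity(self):
        p = gq.ModelParams.zeros(N=4, K=2, M=1, H=1, sigma2_sq=1.0)
        assert np.allclose(gq.covariance(p, 4), np.eye(4))

    def test_hand_expanded_two_gene_case(self):
        p = gq.ModelParams(A=np.zeros((1, 1)), B=[[1.0], [0.0]],
                           C=np.zeros((2, 1)), W=np.zeros((2, 0)),
                           mu_B=np.zeros(2), sigma1_sq=1.0, sigma2_sq=1.0)
        assert np.allclose(gq.covariance(p, 2), [[2.0, 0.0], [0.0, 1.0]])

    def test_matches_dense_arithmetic_oracle(self, rng):
        _, p = random_instance(rng, N=6, M=2, H=2)
        expected = p.sigma1_sq * p.B @ p.B.T + p.W @ p.W.T \
            + p.sigma2_sq * np.eye(6)
        assert np.allclose(gq.covariance(p, 6), expected)

    def test_dimension_mismatch_rejected(self, rng):
        _, p = random_instance(rng)
        with pytest.raises(ValueError):
            gq.covariance(p, 7)


class TestFastInverse:
    def test_diagonal_case(self):
        f = gq.fast_inverse(np.zeros((5, 1)), np.zeros((5, 2)), 1.0, 2.0)
        assert np.allclose(f.dense_inverse(), 0.5 * np.eye(5))
        assert np.allclose(f.S, np.eye(2))

    def test_empty_factors(self):
        f = gq.fast_inverse(np.zeros((4, 0)), np.zeros((4, 0)), 1.0, 4.0)
        assert np.allclose(f.dense_inverse(), np.eye(4) / 4.0)

    def test_requires_positive_sigma2(self):
        with pytest.raises(ValueError):
            gq.fast_inverse(np.zeros((3, 1)), np.zeros((3, 1)), 1.0, 0.0)

    def test_woodbury_matches_dense_oracle_over_many_instances(self):
        """Factorized inverse/log-det vs dense linear algebra, 200 draws."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 13))
            M = int(rng.integers(0, 5))
            H = int(rng.integers(0, 4))
            s1 = float(rng.uniform(0.1, 2.0))
            s2 = float(rng.uniform(0.1, 2.0))
            B = rng.standard_normal((N, M))
            W = rng.standard_normal((N, H))
            f = gq.fast_inverse(B, W, s1, s2)
            Sigma = s1 * B @ B.T + W @ W.T + s2 * np.eye(N)
            assert np.abs(f.dense_inverse() - np.linalg.inv(Sigma)).max() < 1e-8
            assert abs(gq.fast_logdet(f) - np.linalg.slogdet(Sigma)[1]) < 1e-8
            assert np.allclose(f.dense_inverse() @ Sigma, np.eye(N), atol=1e-8)

    def test_trace_inverse_matches_dense(self, rng):
        _, p = random_instance(rng, N=9, M=3, H=2)
        f = gq.fast_inverse(p.B, p.W, p.sigma1_sq, p.sigma2_sq)
        dense = np.trace(np.linalg.inv(gq.covariance(p, 9)))
        assert abs(f.trace_inverse() - dense) < 1e-8


class TestLogdet:
    def test_identity_is_zero(self):
        f = gq.fast_inverse(np.zeros((5, 1)), np.zeros((5, 1)), 1.0, 1.0)
        assert gq.fast_logdet(f) == pytest.approx(0.0)

    def test_scaled_identity(self):
        f = gq.fast_inverse(np.zeros((3, 0)), np.zeros((3, 0)), 1.0, np.e)
        assert gq.fast_logdet(f) == pytest.approx(3.0)


class TestMuB:
    def test_zero_coefficients_give_data_mean(self, rng):
        data, _ = random_instance(rng)
        p = gq.ModelParams.zeros(N=data.N, K=data.K, M=2, H=2)
        assert np.allclose(gq.mu_B_closed_form(p, data), data.z_bar)

    def test_single_sample_exact_residual(self, rng):
        data, p = random_instance(rng, D=1)
        expected = data.Z[:, 0] - p.overall() @ data.X[:, 0]
        assert np.allclose(gq.mu_B_closed_form(p, data), expected)

    def test_beats_perturbed_intercepts(self, rng):
        data, p = random_instance(rng)
        mu = gq.mu_B_closed_form(p, data)
        best = gq.negative_log_likelihood(p, data, mu_B=mu)
        for _ in range(100):
            perturbed = mu + 0.1 * rng.standard_normal(mu.shape)
            assert gq.negative_log_likelihood(p, data, mu_B=perturbed) >= best


class TestLikelihood:
    def test_standard_normal_at_origin(self):
        data = gq.EQTLDataset(X=np.zeros((0, 1)), Z=np.zeros((1, 1)))
        p = gq.ModelParams.zeros(N=1, K=0, M=0, H=0, sigma2_sq=1.0)
        val = gq.negative_log_likelihood(p, data, mu_B=np.zeros(1))
        assert val == pytest.approx(0.5 * np.log(2 * np.pi))

    def test_matches_multivariate_normal_density_oracle(self, rng):
        for _ in range(10):
            data, p = random_instance(rng)
            Sigma = gq.covariance(p, data.N)
            mu_B = gq.mu_B_closed_form(p, data)
            R = p.overall()
            oracle = -sum(
                stats.multivariate_normal.logpdf(
                    data.Z[:, d], R @ data.X[:, d] + mu_B, Sigma)
                for d in range(data.D))
            assert gq.negative_log_likelihood(p, data) == pytest.approx(
                oracle, abs=1e-8)

    def test_translation_invariance_of_centered_form(self, rng):
        data, p = random_instance(rng)
        shifted = gq.EQTLDataset(X=data.X, Z=data.Z + 5.0)
        assert gq.negative_log_likelihood(p, shifted) == pytest.approx(
            gq.negative_log_likelihood(p, data))


class TestPenalizedObjective:
    def test_no_penalty_equals_nll(self, rng):
        data, p = random_instance(rng)
        h = gq.ModelHyper(M=p.M, H=p.H)
        assert gq.penalized_objective(p, data, h) == pytest.approx(
            gq.negative_log_likelihood(p, data))

    def test_elementwise_penalty_oracle(self, rng):
        data, p = random_instance(rng)
        h = gq.ModelHyper(M=p.M, H=p.H, lambda_A=0.3, gamma_B=0.7, alpha_C=1.1)
        pen = sum(0.3 * abs(v) for v in p.A.ravel()) \
            + sum(0.7 * abs(v) for v in p.B.ravel()) \
            + sum(1.1 * abs(v) for v in p.C.ravel())
        assert gq.penalized_objective(p, data, h) == pytest.approx(
            gq.negative_log_likelihood(p, data) + data.D * pen)

    def test_model1_drops_alpha_term(self, rng):
        data, p = random_instance(rng)
        h1 = gq.ModelHyper(M=p.M, H=p.H, alpha_C=100.0, variant="model1")
        h0 = gq.ModelHyper(M=p.M, H=p.H, alpha_C=0.0, variant="model1")
        assert gq.penalized_objective(p, data, h1) == pytest.approx(
            gq.penalized_objective(p, data, h0))

    def test_negative_hyper_rejected(self):
        with pytest.raises(ValueError):
            gq.ModelHyper(M=1, H=1, lambda_A=-0.1)


def _pack(p):
    return np.concatenate([p.A.ravel(), p.B.ravel(), p.C.ravel(),
                           p.W.ravel(), [np.log(p.sigma1_sq)],
                           [np.log(p.sigma2_sq)]])


def _unpack(w, shape):
    N, K, M, H = shape
    o = np.cumsum([0, M * K, N * M, N * K, N * H, 1, 1])
    return gq.ModelParams(
        A=w[o[0]:o[1]].reshape(M, K), B=w[o[1]:o[2]].reshape(N, M),
        C=w[o[2]:o[3]].reshape(N, K), W=w[o[3]:o[4]].reshape(N, H),
        mu_B=np.zeros(N), sigma1_sq=float(np.exp(w[o[4]])),
        sigma2_sq=float(np.exp(w[o[5]])))


class TestSmoothGradient:
    def test_zero_residual_gives_zero_mean_gradient(self, rng):
        data, p = random_instance(rng)
        # construct Z so the centered residual vanishes exactly
        Z = p.overall() @ data.X
        data0 = gq.EQTLDataset(X=data.X, Z=Z)
        g = gq.smooth_gradient(p, data0)
        assert np.allclose(g.C, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_differences(self, seed):
        """Every analytic block vs central differences, 20 random instances."""
        rng = np.random.default_rng(seed)
        data, p = random_instance(rng, N=6, K=5, M=2, H=2, D=12)
        shape = (data.N, data.K, p.M, p.H)
        w0 = _pack(p)
        g = gq.smooth_gradient(p, data, with_sigma2=True)
        analytic = np.concatenate([g.A.ravel(), g.B.ravel(), g.C.ravel(),
                                   g.W.ravel(), [g.log_sigma1_sq],
                                   [g.log_sigma2_sq]])
        eps = 1e-6
        fd = np.zeros_like(w0)
        for i in range(w0.size):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            fd[i] = (gq.negative_log_likelihood(_unpack(wp, shape), data)
                     - gq.negative_log_likelihood(_unpack(wm, shape), data)) \
                / (2 * eps)
        scale = max(np.abs(fd).max(), 1.0)
        assert np.abs(analytic - fd).max() / scale < 1e-5

    def test_duplicating_samples_doubles_gradient(self, rng):
        data, p = random_instance(rng)
        doubled = gq.EQTLDataset(X=np.hstack([data.X, data.X]),
                                 Z=np.hstack([data.Z, data.Z]))
        g1 = gq.smooth_gradient(p, data)
        g2 = gq.smooth_gradient(p, doubled)
        for blk in ("A", "B", "C", "W"):
            assert np.allclose(getattr(g2, blk), 2 * getattr(g1, blk))
        assert g2.log_sigma1_sq == pytest.approx(2 * g1.log_sigma1_sq)


class TestSigma2Update:
    def test_closed_form_when_low_rank_vanishes(self, rng):
        data, _ = random_instance(rng)
        p = gq.ModelParams.zeros(N=data.N, K=data.K, M=0, H=0)
        v = gq.update_sigma2(p, data)
        _, Zc = data.centered()
        expected = np.mean(Zc ** 2)  # mean squared residual
        assert v == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("seed", range(50))
    def test_beats_fine_grid_and_is_stationary(self, seed):
        rng = np.random.default_rng(100 + seed)
        data, p = random_instance(rng)
        v = gq.update_sigma2(p, data)
        loss, dloss = gq.sigma2_profile(p, data)
        grid = np.geomspace(1e-6, 1e3, 10_000)
        assert loss(v) <= min(loss(g) for g in grid) + 1e-10
        # stationarity (or boundary at the floor)
        scale = abs(dloss(v * 1.5)) + abs(dloss(v * 0.5)) + 1.0
        assert abs(dloss(v)) / scale < 1e-4 or v == pytest.approx(1e-6)

    def test_zero_residuals_return_floor(self, rng):
        data, p = random_instance(rng)
        data0 = gq.EQTLDataset(X=data.X, Z=p.overall() @ data.X)
        assert gq.update_sigma2(p, data0, eps_var=1e-6) == pytest.approx(1e-6)

    def test_update_never_increases_loss(self, rng):
        for _ in range(10):
            data, p = random_instance(rng)
            loss, _ = gq.sigma2_profile(p, data)
            before = loss(p.sigma2_sq)
            after = loss(gq.update_sigma2(p, data))
            assert after <= before + 1e-10
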