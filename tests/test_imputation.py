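import numpy as np
import pytest

from stiefnet import imputation as imp
from stiefnet import model, stiefel, vmf


@pytest.fixture()
def tight_params(rng):
    """Parameters whose latent posterior is essentially a point mass at the
    mode and mean weights (huge concentrations, tiny weight variance)."""
    mode = stiefel.sample_uniform(8, 2, rng)
    return model.ModelParams(
        F=vmf.VMFParam(mode * np.array([5e4, 4e4])),
        mu=np.array([9.0, 4.0]),
        sigma_lambda=1e-4,
        sigma_eps=0.5,
    )


class TestMasks:
    def test_random_mask_fraction(self, rng):
        mask = imp.random_edge_mask(10, 0.4, rng)
        assert np.isclose(mask.coverage(), 0.4, atol=0.03)
        assert np.array_equal(mask.observed, mask.observed.T)
        assert np.all(np.diag(mask.observed))

    def test_block_mask_geometry(self):
        mask = imp.block_edge_mask(20, 8)
        # 8*7/2 = 28 hidden pairs of 190 edges, about 15%
        assert mask.n_hidden_edges == 28
        assert np.isclose(mask.coverage(), 28 / 190)
        assert np.all(np.diag(mask.observed))

    def test_asymmetric_mask_rejected(self):
        obs = np.ones((4, 4), dtype=bool)
        obs[0, 1] = False
        with pytest.raises(ValueError):
            imp.EdgeMask(obs)


class TestPosteriorImputation:
    def test_fully_observed_returns_input(self, rng, tight_params):
        A = model.reconstruct(tight_params.mode, tight_params.mu)
        mask = imp.EdgeMask(np.ones((8, 8), dtype=bool))
        res = imp.impute_posterior(A, mask, tight_params, rng=rng)
        assert np.array_equal(res.posterior_mean, A)

    def test_single_entry_matches_conjugate_gaussian(self, rng, tight_params):
        # with the latents pinned by the prior, a hidden entry's posterior is
        # exactly N(reconstruction, sigma_eps^2)
        truth_low = model.reconstruct(tight_params.mode, tight_params.mu)
        A_obs = truth_low.copy()
        obs = np.ones((8, 8), dtype=bool)
        obs[0, 1] = obs[1, 0] = False
        mask = imp.EdgeMask(obs)
        A_obs[0, 1] = A_obs[1, 0] = 0.0
        res = imp.impute_posterior(
            A_obs, mask, tight_params, n_samples=3000, n_burnin=300, rng=rng
        )
        draws = res.samples[:, 0]
        assert abs(np.mean(draws) - truth_low[0, 1]) < 0.05
        assert abs(np.std(draws) / tight_params.sigma_eps - 1.0) < 0.1

    def test_noise_free_recovery(self, rng):
        mode = stiefel.sample_uniform(8, 2, rng)
        params = model.ModelParams(
            F=vmf.VMFParam(mode * np.array([5e4, 4e4])),
            mu=np.array([9.0, 4.0]), sigma_lambda=1e-4, sigma_eps=1e-4,
        )
        truth = model.reconstruct(params.mode, params.mu)
        obs = np.ones((8, 8), dtype=bool)
        obs[6:, 6:] = False
        np.fill_diagonal(obs, True)
        mask = imp.EdgeMask(obs)
        res = imp.impute_posterior(
            truth * mask.observed, mask, params,
            n_samples=300, n_burnin=200, rng=rng,
        )
        assert np.max(np.abs((res.posterior_mean - truth)[mask.hidden])) < 0.01


class TestMAP:
    def test_noise_free_recovery(self, rng):
        mode = stiefel.sample_uniform(8, 2, rng)
        params = model.ModelParams(
            F=vmf.VMFParam(mode * np.array([5e4, 4e4])),
            mu=np.array([9.0, 4.0]), sigma_lambda=1e-4, sigma_eps=1e-4,
        )
        truth = model.reconstruct(params.mode, params.mu)
        obs = np.ones((8, 8), dtype=bool)
        obs[6:, 6:] = False
        np.fill_diagonal(obs, True)
        mask = imp.EdgeMask(obs)
        est, _ = imp.impute_map(truth * mask.observed, mask, params)
        assert np.max(np.abs((est - truth)[mask.hidden])) < 1e-3

    def test_objective_nondecreasing(self, rng, medium_params):
        ds, _ = model.sample_dataset(medium_params, 5, rng, n_burnin=100)
        mask = imp.random_edge_mask(8, 0.3, rng)
        A_obs = ds.matrices * mask.observed
        # objective at the coordinate-ascent starting point (mode, mu)
        M = 5
        X0 = np.broadcast_to(medium_params.mode, (M, 8, 3)).copy()
        lam0 = np.broadcast_to(medium_params.mu, (M, 3)).copy()
        A0 = A_obs.copy()
        A0[:, mask.hidden] = model.reconstruct(X0, lam0)[:, mask.hidden]
        f0 = imp.posterior_log_density(A0, X0, lam0, medium_params)
        est, _ = imp.impute_map(A_obs, mask, medium_params, max_iters=50)
        # recompute the objective at the returned point
        Xf, lamf = imp._init_latents(est, medium_params)
        ff = imp.posterior_log_density(est, Xf, lamf, medium_params)
        # the returned imputation corresponds to a no-worse objective (the
        # internal iterate is at least as good as its re-decomposition)
        assert np.all(ff >= f0 - 1e-6)

    def test_gradients_match_posterior_density(self, rng, medium_params):
        ds, lat = model.sample_dataset(medium_params, 1, rng, n_burnin=100)
        A, X, lam = ds.matrices[0], lat.X[0], lat.lam[0]
        gX = model.grad_loglik_X(A, X, lam, medium_params)
        gl = model.grad_loglik_lam(A, X, lam, medium_params)
        h = 1e-6
        for _ in range(4):
            i, j = rng.integers(8), rng.integers(3)
            Xp = X.copy(); Xp[i, j] += h
            Xm = X.copy(); Xm[i, j] -= h
            fd = (
                imp.posterior_log_density(A, Xp, lam, medium_params)
                - imp.posterior_log_density(A, Xm, lam, medium_params)
            ) / (2 * h)
            assert np.isclose(fd, gX[i, j], rtol=1e-4, atol=1e-4)
        for j in range(3):
            lp = lam.copy(); lp[j] += h
            lm = lam.copy(); lm[j] -= h
            fd = (
                imp.posterior_log_density(A, X, lp, medium_params)
                - imp.posterior_log_density(A, X, lm, medium_params)
            ) / (2 * h)
            assert np.isclose(fd, gl[j], rtol=1e-4, atol=1e-4)


class TestBaselinesAndMetric:
    def test_mean_baseline_identities(self, rng):
        A = rng.standard_normal((1, 5, 5))
        A = A + np.swapaxes(A, 1, 2)
        same = model.AdjacencyDataset(np.repeat(A, 4, axis=0))
        assert np.allclose(imp.baseline_mean_impute(same), A[0])
        pm = model.AdjacencyDataset(np.concatenate([A, -A]))
        assert np.allclose(imp.baseline_mean_impute(pm), 0.0)

    def test_lowrank_truncation(self, rng):
        X = stiefel.sample_uniform(6, 2, rng)
        A = model.reconstruct(X, np.array([5.0, -3.0]))
        assert np.allclose(imp.baseline_lowrank_truncate(A, 2), A, atol=1e-10)
        B = rng.standard_normal((6, 6))
        B = B + B.T
        assert np.allclose(imp.baseline_lowrank_truncate(B, 6), B, atol=1e-10)
        trunc = imp.baseline_lowrank_truncate(B, 2)
        eigs = np.linalg.eigvalsh(trunc)
        assert np.sum(np.abs(eigs) > 1e-10) <= 2

    def test_rrmse_identities(self, rng):
        truth = rng.standard_normal((4, 4))
        truth = truth + truth.T
        obs = np.ones((4, 4), dtype=bool)
        obs[2:, 2:] = False
        np.fill_diagonal(obs, True)
        mask = imp.EdgeMask(obs)
        assert imp.masked_rrmse(truth, truth, mask) == 0.0
        assert np.isclose(imp.masked_rrmse(np.zeros_like(truth), truth, mask), 1.0)
        assert np.isclose(imp.masked_rrmse(2 * truth, truth, mask), 1.0)
        with pytest.raises(ZeroDivisionError):
            imp.masked_rrmse(truth, np.zeros_like(truth), mask)


class TestNoiseCalibration:
    def test_hits_target_ratio(self, rng):
        mu = np.array([15.0, 12.0, 10.0, 8.0, 5.0])
        sig = imp.calibrate_sigma_eps(mu, 9.0, 20, target=0.25, rng=rng)
        # verify by independent Monte Carlo
        check = np.random.default_rng(99)
        lam = mu + 9.0 * check.standard_normal((3000, 5))
        Z = check.standard_normal((3000, 20, 20)) * sig
        E = np.triu(Z) + np.swapaxes(np.triu(Z, k=1), 1, 2)
        ratio = np.mean(
            np.linalg.norm(E, axis=(1, 2)) / np.linalg.norm(lam, axis=1)
        )
        assert abs(ratio - 0.25) < 0.01
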