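import numpy as np
import pytest

from stiefnet import model, stiefel, vmf


class TestReconstruct:
    def test_zero_weights(self, rng):
        X = stiefel.sample_uniform(5, 2, rng)
        assert np.allclose(model.reconstruct(X, np.zeros(2)), 0.0)

    def test_canonical_basis(self):
        X = np.eye(4)[:, :2]
        R = model.reconstruct(X, np.array([3.0, -1.0]))
        assert np.allclose(R, np.diag([3.0, -1.0, 0.0, 0.0]))

    def test_spectrum_matches_weights(self, rng):
        X = stiefel.sample_uniform(6, 3, rng)
        lam = np.array([5.0, -2.0, 1.0])
        R = model.reconstruct(X, lam)
        assert np.allclose(R, R.T)
        eigs = np.sort(np.linalg.eigvalsh(R))
        expected = np.sort(np.concatenate([lam, np.zeros(3)]))
        assert np.allclose(eigs, expected, atol=1e-10)


class TestSampleDataset:
    def test_degenerate_variances_give_exact_spectrum(self, rng, small_params):
        params = model.ModelParams(
            F=small_params.F, mu=small_params.mu,
            sigma_lambda=1e-12, sigma_eps=1e-12,
        )
        ds, _ = model.sample_dataset(params, 5, rng, n_burnin=100)
        for A in ds.matrices:
            top = np.sort(np.linalg.eigvalsh(A))[::-1][:2]
            assert np.allclose(np.sort(top)[::-1], [20.0, 10.0], atol=1e-5)

    def test_weight_mean_converges(self, rng, small_params):
        _, lat = model.sample_dataset(small_params, 4000, rng, n_burnin=200)
        err = np.abs(lat.lam.mean(axis=0) - small_params.mu)
        assert np.all(err < 3 * small_params.sigma_lambda / np.sqrt(4000) + 0.05)

    def test_top_eigenvalues_near_weights(self, rng, small_params):
        ds, lat = model.sample_dataset(small_params, 50, rng, n_burnin=300)
        for A, lam in zip(ds.matrices, lat.lam):
            top = np.sort(np.linalg.eigvalsh(A))[::-1][:2]
            assert np.max(np.abs(np.sort(top)[::-1] - np.sort(lam)[::-1])) < 0.5


class TestLikelihood:
    def test_perfect_fit_is_maximal(self, rng, medium_params):
        X = medium_params.mode
        lam = medium_params.mu.copy()
        A = model.reconstruct(X, lam)
        best = model.complete_log_likelihood(A, X, lam, medium_params)
        for _ in range(50):
            Xp = stiefel.propose_move(X, 0.1, rng)
            lp = lam + 0.5 * rng.standard_normal(lam.shape)
            assert model.complete_log_likelihood(A, Xp, lp, medium_params) <= best

    def test_doubling_sigma_eps_normalization(self, rng, medium_params):
        # with a perfect fit the likelihood drops by count*log(2), where
        # count is the number of free coordinates n(n+1)/2
        X = medium_params.mode
        lam = medium_params.mu
        A = model.reconstruct(X, lam)
        base = model.complete_log_likelihood(A, X, lam, medium_params)
        doubled = model.ModelParams(
            F=medium_params.F, mu=medium_params.mu,
            sigma_lambda=medium_params.sigma_lambda,
            sigma_eps=2 * medium_params.sigma_eps,
        )
        drop = base - model.complete_log_likelihood(A, X, lam, doubled)
        n = medium_params.n
        assert np.isclose(drop, n * (n + 1) / 2 * np.log(2.0), rtol=1e-10)

    def test_gradients_match_finite_differences(self, rng, medium_params):
        ds, lat = model.sample_dataset(medium_params, 1, rng, n_burnin=100)
        A, X, lam = ds.matrices[0], lat.X[0], lat.lam[0]
        gX = model.grad_loglik_X(A, X, lam, medium_params)
        gl = model.grad_loglik_lam(A, X, lam, medium_params)
        h = 1e-6

        def ll(Xv, lv):
            return float(model.complete_log_likelihood(A, Xv, lv, medium_params))

        for _ in range(5):
            i, j = rng.integers(8), rng.integers(3)
            Xp = X.copy(); Xp[i, j] += h
            Xm = X.copy(); Xm[i, j] -= h
            fd = (ll(Xp, lam) - ll(Xm, lam)) / (2 * h)
            assert np.isclose(fd, gX[i, j], rtol=1e-4, atol=1e-4)
        for j in range(3):
            lp = lam.copy(); lp[j] += h
            lm = lam.copy(); lm[j] -= h
            fd = (ll(X, lp) - ll(X, lm)) / (2 * h)
            assert np.isclose(fd, gl[j], rtol=1e-4, atol=1e-4)

    def test_nonpositive_variance_rejected(self, small_params):
        with pytest.raises(ValueError):
            model.ModelParams(
                F=small_params.F, mu=small_params.mu,
                sigma_lambda=0.0, sigma_eps=1.0,
            )


class TestSufficientStats:
    def test_exact_reconstruction_gives_zero_s4(self, rng):
        X = stiefel.sample_uniform(4, 2, rng, size=3)
        lam = rng.standard_normal((3, 2)) * 5
        ds = model.AdjacencyDataset(model.reconstruct(X, lam))
        S = model.suff_stats(ds, model.LatentState(X, lam))
        assert S.s4 < 1e-20

    def test_constant_weights(self, rng):
        X = stiefel.sample_uniform(4, 2, rng, size=5)
        c = np.array([3.0, -1.0])
        lam = np.tile(c, (5, 1))
        ds = model.AdjacencyDataset(model.reconstruct(X, lam))
        S = model.suff_stats(ds, model.LatentState(X, lam))
        assert np.allclose(S.s2, c)
        assert np.isclose(S.s3, np.sum(c**2))

    def test_matches_direct_computation(self, rng, medium_params):
        ds, lat = model.sample_dataset(medium_params, 7, rng, n_burnin=100)
        S = model.suff_stats(ds, lat)
        assert np.allclose(S.s1, lat.X.mean(axis=0))
        assert np.allclose(S.s2, lat.lam.mean(axis=0))
        assert np.isclose(S.s3, np.mean(np.sum(lat.lam**2, axis=1)))
        W = model.edge_weights(8)
        direct = np.mean([
            np.sum(W * (A - model.reconstruct(x, l)) ** 2)
            for A, x, l in zip(ds.matrices, lat.X, lat.lam)
        ])
        assert np.isclose(S.s4, direct)


class TestMStep:
    def test_recovers_gaussian_mle_of_weights(self, rng, medium_params):
        # noise-free data with known latents: the M-step reproduces the
        # closed-form Gaussian MLE (1/N convention) of the weights
        params = model.ModelParams(
            F=medium_params.F, mu=medium_params.mu,
            sigma_lambda=2.0, sigma_eps=1e-9,
        )
        ds, lat = model.sample_dataset(params, 200, rng, n_burnin=200)
        est = model.m_step(model.suff_stats(ds, lat), 8, 3)
        assert np.allclose(est.mu, lat.lam.mean(axis=0), atol=1e-8)
        assert np.isclose(
            est.sigma_lambda,
            np.sqrt(np.mean(np.sum((lat.lam - lat.lam.mean(0)) ** 2, axis=1) / 3)),
            rtol=1e-6,
        )
        assert est.sigma_eps < 1e-4

    def test_zero_weight_scatter_floors_variance(self, rng):
        X = stiefel.sample_uniform(5, 2, rng, size=4)
        lam = np.tile([4.0, 2.0], (4, 1))
        ds = model.AdjacencyDataset(model.reconstruct(X, lam))
        est = model.m_step(model.suff_stats(ds, model.LatentState(X, lam)), 5, 2)
        assert est.sigma_lambda < 1e-5
        assert est.sigma_eps < 1e-5


class TestDiagnosticsAndDof:
    def test_dof_formula(self, rng):
        mode = stiefel.sample_uniform(5, 2, rng)
        params = model.ModelParams(
            F=vmf.VMFParam(mode * 3.0), mu=np.ones(2),
            sigma_lambda=1.0, sigma_eps=1.0,
        )
        assert params.degrees_of_freedom() == 5 * 2 + 2 + 2

    def test_exact_fit_diagnostics(self, rng):
        X = stiefel.sample_uniform(6, 2, rng, size=4)
        lam = np.abs(rng.standard_normal((4, 2))) * 5 + 1
        ds = model.AdjacencyDataset(model.reconstruct(X, lam))
        params = model.ModelParams(
            F=vmf.VMFParam(X[0] * 10.0), mu=lam.mean(0),
            sigma_lambda=1.0, sigma_eps=1.0,
        )
        rep = model.diagnostics(ds, model.LatentState(X, lam), params)
        assert rep["relative_error_mean"] < 1e-10
        assert np.isclose(rep["variance_explained"], 1.0)

    def test_pure_noise_fit_explains_nothing(self, rng):
        A = rng.standard_normal((3, 5, 5))
        A = A + np.swapaxes(A, 1, 2)
        ds = model.AdjacencyDataset(A)
        X = stiefel.sample_uniform(5, 2, rng, size=3)
        lam = np.zeros((3, 2))
        params = model.ModelParams(
            F=vmf.VMFParam(X[0] * 5.0), mu=np.zeros(2),
            sigma_lambda=1.0, sigma_eps=1.0,
        )
        rep = model.diagnostics(ds, model.LatentState(X, lam), params)
        assert np.isclose(rep["relative_error_mean"], 1.0)
        assert np.isclose(rep["variance_explained"], 0.0)

    def test_uniform_baseline_concentration_is_small(self, rng):
        base = model.uniform_baseline_concentration(10, 2, 200, rng)
        # pure Haar frames: far below any genuinely concentrated value
        assert np.all(base < 10.0)


class TestSerialization:
    def test_roundtrip(self, tmp_path, small_params):
        path = tmp_path / "params.zip"
        small_params.save(str(path), extra_meta={"seed": 3})
        loaded = model.ModelParams.load(str(path))
        assert np.allclose(loaded.F.F, small_params.F.F)
        assert np.allclose(loaded.mu, small_params.mu)
        assert loaded.sigma_lambda == small_params.sigma_lambda
        assert loaded.sigma_eps == small_params.sigma_eps


class TestAdjacencyDataset:
    def test_rejects_asymmetric(self, rng):
        A = rng.standard_normal((2, 4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            model.AdjacencyDataset(A)

    def test_mask_weights(self):
        A = np.zeros((1, 3, 3))
        obs = np.ones((3, 3), dtype=bool)
        obs[0, 1] = obs[1, 0] = False
        ds = model.AdjacencyDataset(A, obs)
        assert ds.weight_total == 3 * 4 / 2 - 1  # one pair removed
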