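"""Scikit-learn style estimators wrapping the MCMC-SAEM fits.

``StiefelPatternModel`` fits the single-population decomposition model to a
stack of symmetric adjacency matrices; ``StiefelPatternMixture`` is the
clustering variant.  Both follow the sklearn estimator contract
(``get_params``/``set_params``, ``fit``, trailing-underscore fitted
attributes) so they compose with pipelines and model selection; the module
functions in :mod:`stiefnet.saem` and :mod:`stiefnet.mixture` remain the
underlying implementation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import imputation as imp
from . import mixture as mix_mod
from . import model as model_mod
from . import saem as saem_mod
from .model import AdjacencyDataset
from .saem import SAEMConfig

__all__ = ["StiefelPatternModel", "StiefelPatternMixture"]


def _as_dataset(X, observed=None) -> AdjacencyDataset:
    if isinstance(X, AdjacencyDataset):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError(
            "expected a stack of symmetric matrices with shape (N, n, n), "
            f"got {X.shape}"
        )
    return AdjacencyDataset(X, observed)


class StiefelPatternModel(BaseEstimator):
    """Low-rank pattern decomposition of a population of networks.

    Models each symmetric adjacency matrix as
    ``A = X Diag(lam) X^T + eps`` with the orthonormal pattern frame ``X``
    following a matrix von Mises--Fisher distribution and the weights
    Gaussian; parameters are estimated by MCMC-SAEM.

    Parameters
    ----------
    p : number of rank-one patterns.
    n_iterations, mcmc_steps_per_iter : SAEM loop sizes.
    match_every, match_fraction : greedy column-matching schedule.
    n_hybrid_gradient_iters : gradient-ascent warm-up iterations.
    target_accept : adaptive Metropolis--Hastings target acceptance rate.
    random_state : seed for all randomness.

    Attributes (after fit)
    ----------------------
    F_ : (n, p) vMF parameter; ``mode_`` its projection, ``concentrations_``
        its column norms.
    mu_, sigma_lambda_, sigma_eps_ : weight mean and standard deviations.
    latent_X_, latent_lambda_ : posterior-summary latents per subject.
    result_ : the full :class:`~stiefnet.saem.FitResult` (traces included).
    """

    def __init__(
        self,
        p: int = 5,
        n_iterations: int = 100,
        mcmc_steps_per_iter: int = 20,
        match_every: int = 5,
        match_fraction: float = 1.0 / 3.0,
        n_hybrid_gradient_iters: int = 10,
        target_accept: float = 0.3,
        random_state: int | None = None,
    ) -> None:
        self.p = p
        self.n_iterations = n_iterations
        self.mcmc_steps_per_iter = mcmc_steps_per_iter
        self.match_every = match_every
        self.match_fraction = match_fraction
        self.n_hybrid_gradient_iters = n_hybrid_gradient_iters
        self.target_accept = target_accept
        self.random_state = random_state

    def _config(self) -> SAEMConfig:
        return SAEMConfig(
            n_iterations=self.n_iterations,
            mcmc_steps_per_iter=self.mcmc_steps_per_iter,
            match_every=self.match_every,
            match_fraction=self.match_fraction,
            n_hybrid_gradient_iters=self.n_hybrid_gradient_iters,
            target_accept=self.target_accept,
            seed=self.random_state,
        )

    def fit(self, X, y=None, observed=None):
        dataset = _as_dataset(X, observed)
        rng = np.random.default_rng(self.random_state)
        res = saem_mod.fit(dataset, self.p, self._config(), rng)
        self.result_ = res
        self.params_ = res.params
        self.F_ = res.params.F.F
        self.mode_ = res.params.mode
        self.concentrations_ = res.params.concentrations
        self.mu_ = res.params.mu
        self.sigma_lambda_ = res.params.sigma_lambda
        self.sigma_eps_ = res.params.sigma_eps
        self.latent_X_ = res.posterior_X
        self.latent_lambda_ = res.posterior_lam
        self.n_nodes_ = dataset.n_nodes
        self.degrees_of_freedom_ = res.params.degrees_of_freedom()
        return self

    def sample(self, N: int, random_state: int | None = None):
        """Draw N synthetic matrices from the fitted model."""
        self._check_fitted()
        rng = np.random.default_rng(random_state)
        dataset, _ = model_mod.sample_dataset(self.params_, N, rng)
        return dataset.matrices

    def impute(
        self,
        A_obs: np.ndarray,
        observed: np.ndarray,
        method: str = "posterior",
        random_state: int | None = None,
        **kwargs,
    ):
        """Infer masked entries of new matrices under the fitted model."""
        self._check_fitted()
        mask = imp.EdgeMask(observed)
        if method == "posterior":
            rng = np.random.default_rng(random_state)
            return imp.impute_posterior(
                A_obs, mask, self.params_, rng=rng, **kwargs
            ).posterior_mean
        if method == "map":
            return imp.impute_map(A_obs, mask, self.params_, **kwargs)[0]
        raise ValueError(f"unknown imputation method {method!r}")

    def score(self, X, y=None):
        """Mean complete log-likelihood at spectrally estimated latents.

        A deterministic proxy for model fit (higher is better); useful for
        coarse model comparison, e.g. across values of ``p``.
        """
        self._check_fitted()
        dataset = _as_dataset(X)
        Xl, lam = imp._init_latents(dataset.matrices, self.params_)
        ll = model_mod.complete_log_likelihood(
            dataset.matrices, Xl, lam, self.params_, dataset.observed
        )
        return float(np.mean(ll))

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")


class StiefelPatternMixture(ClusterMixin, BaseEstimator):
    """Mixture of pattern-decomposition models, fitted by tempered MCMC-SAEM.

    Clusters a population of networks whose variability is multi-modal;
    ``labels_`` holds the MAP cluster of each training matrix and
    ``responsibilities_`` the posterior cluster probabilities.
    """

    def __init__(
        self,
        p: int = 5,
        K: int = 2,
        n_iterations: int = 300,
        mcmc_steps_per_iter: int = 20,
        match_every: int = 5,
        match_fraction: float = 1.0 / 3.0,
        n_hybrid_gradient_iters: int = 10,
        target_accept: float = 0.3,
        random_state: int | None = None,
    ) -> None:
        self.p = p
        self.K = K
        self.n_iterations = n_iterations
        self.mcmc_steps_per_iter = mcmc_steps_per_iter
        self.match_every = match_every
        self.match_fraction = match_fraction
        self.n_hybrid_gradient_iters = n_hybrid_gradient_iters
        self.target_accept = target_accept
        self.random_state = random_state

    def fit(self, X, y=None, observed=None):
        dataset = _as_dataset(X, observed)
        rng = np.random.default_rng(self.random_state)
        config = SAEMConfig(
            n_iterations=self.n_iterations,
            mcmc_steps_per_iter=self.mcmc_steps_per_iter,
            match_every=self.match_every,
            match_fraction=self.match_fraction,
            n_hybrid_gradient_iters=self.n_hybrid_gradient_iters,
            target_accept=self.target_accept,
            seed=self.random_state,
        )
        res = mix_mod.fit_mixture(dataset, self.p, self.K, config, rng)
        self.result_ = res
        self.mixture_params_ = res.params
        self.weights_ = res.params.pi
        self.labels_ = res.labels
        self.responsibilities_ = res.responsibilities
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
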