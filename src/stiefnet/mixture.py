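"""Mixture of decomposition models for heterogeneous network populations.

Each subject k carries a cluster label z(k) ~ Categorical(pi); conditional on
z(k) = c the adjacency matrix follows the single-population model with
parameters theta_c.  Estimation extends MCMC-SAEM with a tempered label
update: the cluster posterior probabilities raised to 1/T_t (with
T_t = 1 + 50/t^0.6 decreasing to 1) propose label moves that are accepted
against the exact conditional, which encourages moves between clusters early
on without disturbing the invariant law.  Clusters are initialized with K-Means on the vectorized upper
triangles; the component modes are mutually re-aligned by greedy column
matching every few iterations so that subjects can drift between clusters
through small Metropolis steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from . import saem as saem_mod
from . import vmf
from .model import (
    AdjacencyDataset,
    LatentState,
    ModelParams,
    complete_log_likelihood,
    m_step,
    suff_stats,
)
from .saem import (
    AdaptiveKernelState,
    SAEMConfig,
    adapt_step,
    gibbs_sweep,
    greedy_column_match,
    sa_weight,
)

__all__ = [
    "MixtureParams",
    "MixtureFitResult",
    "sample_mixture_dataset",
    "posterior_cluster_probs",
    "temperature",
    "fit_mixture",
    "label_accuracy",
]


@dataclass
class MixtureParams:
    """K component parameter sets plus mixing probabilities."""

    components: list[ModelParams]
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        K = len(self.components)
        if self.pi.shape != (K,):
            raise ValueError("pi must have one entry per component")
        if np.any(self.pi < 0) or abs(float(np.sum(self.pi)) - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def n(self) -> int:
        return self.components[0].n

    @property
    def p(self) -> int:
        return self.components[0].p


@dataclass
class MixtureFitResult:
    """Output of the tempered mixture MCMC-SAEM."""

    params: MixtureParams
    labels: np.ndarray  # (N,) MAP labels
    responsibilities: np.ndarray  # (N, K)
    latents: LatentState
    traces: dict[str, np.ndarray] = field(default_factory=dict)


def sample_mixture_dataset(
    mix: MixtureParams,
    N: int,
    rng: np.random.Generator,
    n_burnin: int = 600,
) -> tuple[AdjacencyDataset, LatentState, np.ndarray]:
    """Ancestral sampling: labels, then per-cluster latents and matrices."""
    from .model import sample_dataset

    labels = rng.choice(mix.K, size=N, p=mix.pi)
    n, p = mix.n, mix.p
    X = np.empty((N, n, p))
    lam = np.empty((N, p))
    A = np.empty((N, n, n))
    for c in range(mix.K):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        ds_c, lat_c = sample_dataset(
            mix.components[c], idx.size, rng, n_burnin=n_burnin
        )
        A[idx] = ds_c.matrices
        X[idx] = lat_c.X
        lam[idx] = lat_c.lam
    return AdjacencyDataset(A), LatentState(X, lam), labels


def _loglik_matrix(
    A: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    mix: MixtureParams,
    observed: np.ndarray | None,
) -> np.ndarray:
    """(N, K) complete log-likelihoods; the per-component vMF normalizing
    constants do NOT cancel across clusters and are included."""
    cols = [
        complete_log_likelihood(A, X, lam, comp, observed)
        for comp in mix.components
    ]
    return np.stack(cols, axis=-1)


def posterior_cluster_probs(
    A: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    mix: MixtureParams,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior label probabilities given the latents, one row per subject.

    Proportional to pi_c * exp(complete log-likelihood under theta_c).
    Rows whose weights all underflow fall back to the uniform distribution
    with a warning.
    """
    A = np.asarray(A, dtype=float)
    single = A.ndim == 2
    logw = np.log(mix.pi) + _loglik_matrix(A, X, lam, mix, observed)
    logw = np.atleast_2d(logw)
    bad = ~np.all(np.isfinite(logw), axis=1)
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} subjects with degenerate cluster weights; "
            "using uniform probabilities",
            RuntimeWarning,
        )
        logw[bad] = 0.0
    probs = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return probs[0] if single else probs


def temperature(t: int) -> float:
    """Tempering profile T_t = 1 + 50 / t^0.6 (decreasing to 1)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return 1.0 + 50.0 / t**0.6


def _tempered_sample(
    probs: np.ndarray, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample labels from probs**(1/T) renormalized, vectorized over rows."""
    if T != 1.0:
        w = probs ** (1.0 / T)
        probs = w / np.sum(w, axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((probs.shape[0], 1))
    return np.sum(u > cum, axis=1).astype(int)


def _tempered_label_move(
    probs: np.ndarray,
    T: float,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Metropolized tempered label update.

    The flattened distribution probs**(1/T) proposes a new label for every
    subject, and the proposal is accepted against the exact conditional
    ``probs`` — so the invariant law of the label chain is the true posterior
    while high temperatures still push subjects to explore other clusters.
    At T = 1 the proposal equals the target and every move is accepted,
    recovering a plain Gibbs draw.
    """
    N = probs.shape[0]
    prop = _tempered_sample(probs, T, rng)
    if T == 1.0:
        return prop
    w = probs ** (1.0 / T)
    q = w / np.sum(w, axis=1, keepdims=True)
    rows = np.arange(N)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_acc = (
            np.log(probs[rows, prop])
            - np.log(probs[rows, labels])
            + np.log(q[rows, labels])
            - np.log(q[rows, prop])
        )
    log_acc = np.where(np.isfinite(log_acc), log_acc, 0.0)
    accept = np.log(rng.random(N)) < log_acc
    out = labels.copy()
    out[accept] = prop[accept]
    return out


def label_accuracy(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Fraction of agreements maximized over relabelings of the prediction.

    The optimal label permutation is an assignment problem on the confusion
    matrix, solved exactly with the Hungarian algorithm (equivalent to
    exhaustive enumeration over the K! permutations).
    """
    from scipy.optimize import linear_sum_assignment

    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have the same length")
    K = int(max(true_labels.max(), predicted_labels.max())) + 1
    conf = np.zeros((K, K))
    np.add.at(conf, (predicted_labels, true_labels), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum()) / true_labels.size


def _kmeans_labels(
    dataset: AdjacencyDataset, K: int, rng: np.random.Generator
) -> np.ndarray:
    n = dataset.n_nodes
    iu = np.triu_indices(n)
    feats = dataset.masked()[:, iu[0], iu[1]]
    km = KMeans(
        n_clusters=K,
        n_init=10,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return km.fit_predict(feats)


def _align_components(mix_components: list[ModelParams]) -> None:
    """Mutually align component modes (permute/sign-flip F columns, permute mu)."""
    ref = mix_components[0].mode
    for c in range(1, len(mix_components)):
        comp = mix_components[c]
        perm, signs, _ = greedy_column_match(comp.mode, ref)
        Fa = comp.F.F[:, perm] * signs
        mix_components[c] = ModelParams(
            F=vmf.VMFParam(Fa),
            mu=comp.mu[perm],
            sigma_lambda=comp.sigma_lambda,
            sigma_eps=comp.sigma_eps,
        )


def fit_mixture(
    dataset: AdjacencyDataset,
    p: int,
    K: int,
    config: SAEMConfig | None = None,
    rng: np.random.Generator | None = None,
    init_labels: np.ndarray | None = None,
    temper: bool = True,
) -> MixtureFitResult:
    """Fit a K-component mixture of decomposition models by tempered MCMC-SAEM.

    K-Means on the vectorized upper triangles initializes the labels; each
    cluster is then initialized spectrally as in the single-population fit.
    The main loop alternates per-cluster Gibbs sweeps of the latents, a
    tempered draw of the labels from their posterior, greedy column matching
    (subject frames to their cluster mode, and cluster modes to each other),
    per-cluster stochastic approximation of the sufficient statistics plus
    the label frequencies, and per-cluster M-steps with pi set to the
    averaged frequencies.  ``K=1`` delegates to the single-population fit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if config is None:
        config = SAEMConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if K == 1:
        res = saem_mod.fit(dataset, p, config, rng)
        N = dataset.N
        return MixtureFitResult(
            params=MixtureParams([res.params], np.array([1.0])),
            labels=np.zeros(N, dtype=int),
            responsibilities=np.ones((N, 1)),
            latents=res.latents,
            traces=res.traces,
        )

    N, n = dataset.N, dataset.n_nodes
    T = config.n_iterations
    if init_labels is not None:
        labels = np.asarray(init_labels, dtype=int).copy()
    else:
        labels = _kmeans_labels(dataset, K, rng)

    # -- spectral initialization -------------------------------------------
    # All subjects are aligned to ONE global reference frame so that weight
    # slots correspond to pattern identity across clusters; aligning each
    # cluster to its own leading eigenvalue order would make every cluster
    # mean look alike and erase the between-cluster structure before the
    # first M-step.
    global_params, latents = saem_mod.initialize(dataset, p)

    components: list[ModelParams] = []
    for c in range(K):
        idx = np.flatnonzero(labels == c)
        if idx.size >= 2:
            sub = AdjacencyDataset(dataset.matrices[idx], dataset.observed)
            S = suff_stats(sub, LatentState(latents.X[idx], latents.lam[idx]))
            components.append(m_step(S, n, p, obs_weight=dataset.weight_total))
        else:
            components.append(global_params)
    pi = np.bincount(labels, minlength=K).astype(float) / N

    # -- hybrid gradient iterations per cluster ----------------------------
    for _ in range(config.n_hybrid_gradient_iters):
        for c in range(K):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:
                continue
            sub = AdjacencyDataset(dataset.matrices[idx], dataset.observed)
            lat_c = LatentState(latents.X[idx], latents.lam[idx])
            saem_mod._hybrid_gradient_pass(sub, lat_c, components[c])
            latents.X[idx] = lat_c.X
            latents.lam[idx] = lat_c.lam
        for c in range(K):
            idx = np.flatnonzero(labels == c)
            if idx.size < 2:
                continue
            sub = AdjacencyDataset(dataset.matrices[idx], dataset.observed)
            S = suff_stats(sub, LatentState(latents.X[idx], latents.lam[idx]))
            components[c] = m_step(
                S, n, p, obs_weight=dataset.weight_total, prev=components[c]
            )

    kernel = AdaptiveKernelState(
        math.log(config.initial_step_X), math.log(config.initial_step_lambda)
    )
    S_bar = [None] * K
    Spi_bar = pi.copy()
    match_until = math.ceil(config.match_fraction * T)
    mix = MixtureParams(components, pi)
    traces: dict[str, list] = {"pi": [], "sigma_eps": [], "accept_X": []}

    for t in range(1, T + 1):
        # latent sweeps, per cluster under its own parameters
        rate_X = rate_lam = 0.0
        for c in range(K):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:
                continue
            latents, rates = gibbs_sweep(
                dataset,
                latents,
                mix.components[c],
                kernel,
                config.mcmc_steps_per_iter,
                rng,
                subset=idx,
            )
            rate_X += rates["accept_X"] * idx.size / N
            rate_lam += rates["accept_lambda"] * idx.size / N
        kernel = adapt_step(kernel, rate_X, rate_lam, t, config.target_accept)

        # tempered label update
        probs = posterior_cluster_probs(
            dataset.matrices, latents.X, latents.lam, mix, dataset.observed
        )
        labels = _tempered_label_move(
            probs, temperature(t) if temper else 1.0, labels, rng
        )

        # alignment: subjects to their cluster mode, clusters to each other
        if t % config.match_every == 0:
            _align_components(mix.components)
            if config.match_enabled and t <= match_until:
                for c in range(K):
                    idx = np.flatnonzero(labels == c)
                    if idx.size:
                        saem_mod._align_latents_to(
                            latents, mix.components[c].mode, subset=idx
                        )

        # stochastic approximation + M-step, per cluster
        alpha = sa_weight(t, T)
        counts = np.bincount(labels, minlength=K).astype(float)
        Spi_bar = (1.0 - alpha) * Spi_bar + alpha * counts / N
        new_components = list(mix.components)
        for c in range(K):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:
                warnings.warn(
                    f"cluster {c} empty at iteration {t}; keeping parameters",
                    RuntimeWarning,
                )
                continue
            sub = AdjacencyDataset(dataset.matrices[idx], dataset.observed)
            S = suff_stats(sub, LatentState(latents.X[idx], latents.lam[idx]))
            S_bar[c] = S if S_bar[c] is None else S_bar[c].blend(S, alpha)
            new_components[c] = m_step(
                S_bar[c], n, p,
                obs_weight=dataset.weight_total, prev=mix.components[c],
            )
        pi_hat = Spi_bar / np.sum(Spi_bar)
        mix = MixtureParams(new_components, pi_hat)

        traces["pi"].append(pi_hat.copy())
        traces["sigma_eps"].append([comp.sigma_eps for comp in mix.components])
        traces["accept_X"].append(rate_X)

    responsibilities = posterior_cluster_probs(
        dataset.matrices, latents.X, latents.lam, mix, dataset.observed
    )
    labels = np.argmax(responsibilities, axis=1)
    return MixtureFitResult(
        params=mix,
        labels=labels,
        responsibilities=responsibilities,
        latents=latents,
        traces={k: np.asarray(v) for k, v in traces.items()},
    )
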