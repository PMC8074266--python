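"""Maximum-likelihood estimation by MCMC-SAEM.

The E-step expectation of the sufficient statistics is replaced by a
Robbins--Monro average over samples of the latent variables produced by a
Metropolis-within-Gibbs sampler (projected Gaussian random walk on the
Stiefel frames, symmetric Gaussian perturbations on the weights; both kept
as Metropolis--Hastings updates rather than exact conditionals, which mixes
faster in practice).  Proposal step sizes adapt on the log scale toward a
target acceptance rate.

Two devices deal with the permutation/sign non-identifiability of the
columns: a greedy column-matching step that re-aligns each subject's frame
to the current mode during the early iterations, and a spectral
initialization followed by a few hybrid iterations where the X-update is a
Riemannian gradient-ascent step instead of an MCMC move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import stiefel
from .model import (
    AdjacencyDataset,
    LatentState,
    ModelParams,
    SufficientStats,
    complete_log_likelihood,
    grad_loglik_X,
    m_step,
    reconstruct,
    suff_stats,
)

__all__ = [
    "SAEMConfig",
    "AdaptiveKernelState",
    "FitResult",
    "sa_weight",
    "adapt_step",
    "gibbs_sweep",
    "greedy_column_match",
    "initialize",
    "fit",
]


@dataclass
class SAEMConfig:
    """Tuning knobs of the MCMC-SAEM loop."""

    n_iterations: int = 100
    mcmc_steps_per_iter: int = 20
    match_every: int = 5
    match_fraction: float = 1.0 / 3.0
    n_hybrid_gradient_iters: int = 10
    target_accept: float = 0.3
    seed: int | None = None
    initial_step_X: float = 0.1
    initial_step_lambda: float = 0.5
    #: fraction of iterations after which posterior summaries are accumulated
    posterior_from: float = 0.5
    #: disable the greedy column-matching step (ablation experiments)
    match_enabled: bool = True
    #: initialize latents at random instead of spectrally (ablation)
    random_init: bool = False

    def __post_init__(self) -> None:
        if min(
            self.n_iterations,
            self.mcmc_steps_per_iter,
            self.match_every,
            self.n_hybrid_gradient_iters + 1,
        ) < 1:
            raise ValueError("iteration counts must be positive")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class AdaptiveKernelState:
    """Log step sizes of the two MH kernels and their acceptance tallies."""

    log_step_X: float
    log_step_lambda: float
    accept_X: int = 0
    total_X: int = 0
    accept_lambda: int = 0
    total_lambda: int = 0

    @property
    def step_X(self) -> float:
        return float(np.exp(self.log_step_X))

    @property
    def step_lambda(self) -> float:
        return float(np.exp(self.log_step_lambda))


def sa_weight(t: int, T: int) -> float:
    """Robbins--Monro weight: 1 during the first half, then (t - T/2)^-0.6."""
    if not (1 <= t <= T):
        raise ValueError(f"need 1 <= t <= T, got t={t}, T={T}")
    half = T // 2
    if t <= half:
        return 1.0
    return float((t - half) ** -0.6)


def _adapted_log_step(
    log_step: float, accept_rate: float, t: int, target: float
) -> float:
    ell = 1.0 if accept_rate > target else -1.0
    return log_step + ell / (2.0 * t**0.6)


def adapt_step(
    state: AdaptiveKernelState,
    accept_rate_X: float,
    accept_rate_lambda: float,
    t: int,
    target: float,
) -> AdaptiveKernelState:
    """Increment both log step sizes by +-1/(2 t^0.6) toward the target
    acceptance rate (ties count as too-low acceptance) and reset tallies."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return AdaptiveKernelState(
        log_step_X=_adapted_log_step(state.log_step_X, accept_rate_X, t, target),
        log_step_lambda=_adapted_log_step(
            state.log_step_lambda, accept_rate_lambda, t, target
        ),
    )


# ---------------------------------------------------------------------------
# Gibbs sweep
# ---------------------------------------------------------------------------


def _obs_sq(A: np.ndarray, X: np.ndarray, lam: np.ndarray, weights) -> np.ndarray:
    R = A - reconstruct(X, lam)
    if weights is None:
        return np.einsum("...ij,...ij->...", R, R)
    return np.einsum("...ij,...ij,ij->...", R, R, weights)


def gibbs_sweep(
    dataset: AdjacencyDataset,
    latents: LatentState,
    params: ModelParams,
    kernel_state: AdaptiveKernelState,
    n_steps: int,
    rng: np.random.Generator,
    subset: np.ndarray | None = None,
) -> tuple[LatentState, dict[str, float]]:
    """Run ``n_steps`` Metropolis-within-Gibbs updates for every subject.

    Each step alternates one full-frame X proposal (projected Gaussian walk)
    and one full-vector lam proposal (symmetric Gaussian), both accepted
    with the exp(delta complete-log-likelihood) ratio; the invariant law is
    the posterior of the latents given the data at the current parameters.
    Updates are vectorized across subjects.  ``subset`` restricts the sweep
    to the given subject indices (used by the mixture loop); acceptance
    tallies accumulate into ``kernel_state``.  Non-finite likelihood changes
    reject the move.
    """
    idx = np.arange(dataset.N) if subset is None else np.asarray(subset)
    m = idx.size
    if m == 0:
        return latents, {"accept_X": float("nan"), "accept_lambda": float("nan")}
    A = dataset.matrices[idx]
    obs = dataset.weights
    X = latents.X[idx].copy()
    lam = latents.lam[idx].copy()
    F = params.F.F
    mu = params.mu
    inv2se = 0.5 / params.sigma_eps**2
    inv2sl = 0.5 / params.sigma_lambda**2

    cur_sq = _obs_sq(A, X, lam, obs)
    cur_tr = np.einsum("kij,ij->k", X, F)
    acc_X = acc_lam = 0
    step_X = kernel_state.step_X
    step_lam = kernel_state.step_lambda
    for _ in range(n_steps):
        # -- X move --
        prop = stiefel.propose_move(X, step_X, rng)
        prop_sq = _obs_sq(A, prop, lam, obs)
        prop_tr = np.einsum("kij,ij->k", prop, F)
        delta = inv2se * (cur_sq - prop_sq) + (prop_tr - cur_tr)
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        take = np.log(rng.random(m)) < delta
        X[take] = prop[take]
        cur_sq[take] = prop_sq[take]
        cur_tr[take] = prop_tr[take]
        acc_X += int(np.sum(take))
        # -- lam move --
        lam_prop = lam + step_lam * rng.standard_normal(lam.shape)
        prop_sq = _obs_sq(A, X, lam_prop, obs)
        delta = inv2se * (cur_sq - prop_sq) + inv2sl * (
            np.sum((lam - mu) ** 2, axis=1) - np.sum((lam_prop - mu) ** 2, axis=1)
        )
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        take = np.log(rng.random(m)) < delta
        lam[take] = lam_prop[take]
        cur_sq[take] = prop_sq[take]
        acc_lam += int(np.sum(take))

    latents.X[idx] = X
    latents.lam[idx] = lam
    kernel_state.accept_X += acc_X
    kernel_state.total_X += n_steps * m
    kernel_state.accept_lambda += acc_lam
    kernel_state.total_lambda += n_steps * m
    return latents, {
        "accept_X": acc_X / (n_steps * m),
        "accept_lambda": acc_lam / (n_steps * m),
    }


# ---------------------------------------------------------------------------
# Column matching
# ---------------------------------------------------------------------------


def greedy_column_match(
    X: np.ndarray, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy permutation/sign alignment of the columns of X to those of M.

    Repeatedly picks the unassigned pair (reference column i, sample column
    j) with the greatest absolute inner product (ties broken by lowest
    row-major index), assigns column j to slot i with the sign of the inner
    product, and removes both from play.

    Returns ``(perm, signs, X_aligned)`` with
    ``X_aligned[:, i] = signs[i] * X[:, perm[i]]``.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError("X and M must have the same shape")
    p = X.shape[1]
    C = M.T @ X
    absC = np.abs(C).copy()
    perm = np.empty(p, dtype=int)
    signs = np.empty(p)
    for _ in range(p):
        flat = int(np.argmax(absC))
        i, j = divmod(flat, p)
        perm[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        absC[i, :] = -np.inf
        absC[:, j] = -np.inf
    X_aligned = X[:, perm] * signs
    return perm, signs, X_aligned


def _align_latents_to(latents: LatentState, M: np.ndarray, subset=None) -> None:
    """Align every subject frame (and its weights) to the reference mode M."""
    idx = range(latents.N) if subset is None else subset
    for k in idx:
        perm, signs, Xa = greedy_column_match(latents.X[k], M)
        latents.X[k] = Xa
        latents.lam[k] = latents.lam[k][perm]


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize(
    dataset: AdjacencyDataset, p: int
) -> tuple[ModelParams, LatentState]:
    """Spectral initialization: per-subject dominant eigenpairs.

    Keeps the p eigenpairs of largest absolute eigenvalue (weights may be
    negative), ordered by decreasing magnitude, aligns every frame to the
    first subject's, and fits initial parameters by one M-step.
    """
    n = dataset.n_nodes
    if dataset.N < 2:
        raise ValueError("need at least 2 subjects to initialize")
    if n < p:
        raise ValueError(f"p={p} exceeds the number of nodes n={n}")
    w, V = np.linalg.eigh(dataset.masked())
    order = np.argsort(-np.abs(w), axis=1)[:, :p]  # (N, p)
    lam = np.take_along_axis(w, order, axis=1)
    X = np.take_along_axis(V, order[:, None, :], axis=2)
    latents = LatentState(X, lam)
    _align_latents_to(latents, latents.X[0], subset=range(1, dataset.N))
    params = m_step(
        suff_stats(dataset, latents), n, p, obs_weight=dataset.weight_total
    )
    return params, latents


def _random_init(
    dataset: AdjacencyDataset, p: int, rng: np.random.Generator
) -> tuple[ModelParams, LatentState]:
    # Worst-case initialization used in ablation studies: uniform frames,
    # weights drawn around the data's eigenvalue scale.
    n = dataset.n_nodes
    X = stiefel.sample_uniform(n, p, rng, size=dataset.N)
    scale = float(np.std(np.linalg.eigvalsh(dataset.masked())))
    lam = scale * rng.standard_normal((dataset.N, p))
    latents = LatentState(X, lam)
    params = m_step(
        suff_stats(dataset, latents), n, p, obs_weight=dataset.weight_total
    )
    return params, latents


# ---------------------------------------------------------------------------
# Hybrid gradient iterations
# ---------------------------------------------------------------------------


def _hybrid_gradient_pass(
    dataset: AdjacencyDataset,
    latents: LatentState,
    params: ModelParams,
    initial_step: float = 1e-2,
    max_halvings: int = 12,
) -> None:
    """Replace the X MCMC move with one Riemannian ascent step per subject.

    Backtracking halves the step until the per-subject objective (the terms
    of the complete log-likelihood that depend on X) does not decrease.
    """
    A = dataset.matrices
    obs = dataset.weights
    X = latents.X
    lam = latents.lam
    inv2se = 0.5 / params.sigma_eps**2

    def objective(Xc):
        return -inv2se * _obs_sq(A, Xc, lam, obs) + np.einsum(
            "kij,ij->k", Xc, params.F.F
        )

    G = grad_loglik_X(A, X, lam, params, obs)
    f0 = objective(X)
    steps = np.full(dataset.N, initial_step)
    new_X = X.copy()
    pending = np.ones(dataset.N, dtype=bool)
    for _ in range(max_halvings):
        if not np.any(pending):
            break
        idx = np.flatnonzero(pending)
        # step size varies per subject: scale the tangent directly, then retract
        xi = stiefel.tangent_project(X[idx], G[idx])
        cand = stiefel.project_to_stiefel(X[idx] + steps[idx, None, None] * xi)
        fc = -inv2se * _obs_sq(A[idx], cand, lam[idx], obs) + np.einsum(
            "kij,ij->k", cand, params.F.F
        )
        ok = fc >= f0[idx]
        new_X[idx[ok]] = cand[ok]
        pending[idx[ok]] = False
        steps[idx[~ok]] *= 0.5
    latents.X[...] = new_X


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Output of the MCMC-SAEM fit."""

    params: ModelParams
    latents: LatentState
    posterior_X: np.ndarray  # (N, n, p) projected posterior-mean frames
    posterior_lam: np.ndarray  # (N, p) posterior-mean weights
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def concentrations(self) -> np.ndarray:
        return self.params.concentrations


def fit(
    dataset: AdjacencyDataset,
    p: int,
    config: SAEMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit the decomposition model to a data set by MCMC-SAEM.

    Spectral initialization, a few hybrid iterations with gradient-ascent
    X-updates, then the main loop: Gibbs sweep, greedy column matching of
    every subject frame to the current mode (every ``match_every`` iterations
    during the first ``match_fraction`` of the run), stochastic approximation
    of the sufficient statistics, and the closed-form M-step.  Posterior
    summaries average the latent samples over the second half of the
    iterations, projecting the mean frame back onto the manifold.
    """
    if config is None:
        config = SAEMConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.n_iterations
    n = dataset.n_nodes

    if config.random_init:
        params, latents = _random_init(dataset, p, rng)
    else:
        params, latents = initialize(dataset, p)

    for _ in range(config.n_hybrid_gradient_iters):
        _hybrid_gradient_pass(dataset, latents, params)
        kernel_tmp = AdaptiveKernelState(
            math.log(config.initial_step_X), math.log(config.initial_step_lambda)
        )
        _sweep_lambda_only(dataset, latents, params, kernel_tmp, 1, rng)
        params = m_step(
            suff_stats(dataset, latents), n, p,
            obs_weight=dataset.weight_total, prev=params,
        )

    kernel = AdaptiveKernelState(
        math.log(config.initial_step_X), math.log(config.initial_step_lambda)
    )
    S_bar = suff_stats(dataset, latents)
    match_until = math.ceil(config.match_fraction * T)
    traces: dict[str, list] = {
        k: []
        for k in (
            "mu",
            "concentrations",
            "sigma_lambda",
            "sigma_eps",
            "accept_X",
            "accept_lambda",
            "step_X",
            "step_lambda",
        )
    }
    post_from = int(config.posterior_from * T)
    X_sum = np.zeros_like(latents.X)
    lam_sum = np.zeros_like(latents.lam)
    n_post = 0

    for t in range(1, T + 1):
        latents, rates = gibbs_sweep(
            dataset, latents, params, kernel, config.mcmc_steps_per_iter, rng
        )
        kernel = adapt_step(
            kernel, rates["accept_X"], rates["accept_lambda"], t, config.target_accept
        )
        if (
            config.match_enabled
            and t <= match_until
            and t % config.match_every == 0
        ):
            _align_latents_to(latents, params.mode)
        S = suff_stats(dataset, latents)
        S_bar = S_bar.blend(S, sa_weight(t, T))
        params = m_step(S_bar, n, p, obs_weight=dataset.weight_total, prev=params)
        if not (
            np.all(np.isfinite(params.F.F))
            and np.all(np.isfinite(params.mu))
            and np.isfinite(params.sigma_eps)
        ):
            raise RuntimeError(
                f"non-finite parameters at iteration {t}; traces: "
                f"{ {k: v[-3:] for k, v in traces.items()} }"
            )
        if t > post_from:
            X_sum += latents.X
            lam_sum += latents.lam
            n_post += 1
        traces["mu"].append(params.mu.copy())
        traces["concentrations"].append(np.sort(params.concentrations)[::-1])
        traces["sigma_lambda"].append(params.sigma_lambda)
        traces["sigma_eps"].append(params.sigma_eps)
        traces["accept_X"].append(rates["accept_X"])
        traces["accept_lambda"].append(rates["accept_lambda"])
        traces["step_X"].append(kernel.step_X)
        traces["step_lambda"].append(kernel.step_lambda)

    if n_post == 0:
        X_sum, lam_sum, n_post = latents.X.copy(), latents.lam.copy(), 1
    posterior_X = stiefel.project_to_stiefel(X_sum / n_post)
    posterior_lam = lam_sum / n_post
    return FitResult(
        params=params,
        latents=latents,
        posterior_X=posterior_X,
        posterior_lam=posterior_lam,
        traces={k: np.asarray(v) for k, v in traces.items()},
    )


def _sweep_lambda_only(
    dataset: AdjacencyDataset,
    latents: LatentState,
    params: ModelParams,
    kernel_state: AdaptiveKernelState,
    n_steps: int,
    rng: np.random.Generator,
) -> None:
    """Weight-only MH updates, used inside the hybrid gradient iterations."""
    A = dataset.matrices
    obs = dataset.weights
    lam = latents.lam
    mu = params.mu
    inv2se = 0.5 / params.sigma_eps**2
    inv2sl = 0.5 / params.sigma_lambda**2
    cur_sq = _obs_sq(A, latents.X, lam, obs)
    step = kernel_state.step_lambda
    for _ in range(n_steps):
        prop = lam + step * rng.standard_normal(lam.shape)
        prop_sq = _obs_sq(A, latents.X, prop, obs)
        delta = inv2se * (cur_sq - prop_sq) + inv2sl * (
            np.sum((lam - mu) ** 2, axis=1) - np.sum((prop - mu) ** 2, axis=1)
        )
        take = np.log(rng.random(lam.shape[0])) < delta
        lam[take] = prop[take]
        cur_sq[take] = prop_sq[take]
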