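"""The generative model for data sets of symmetric adjacency matrices.

Each of the N matrices decomposes as

    A(k) = X(k) Diag(lam(k)) X(k)^T + eps(k)

with X(k) ~ vMF(F) on V(n, p), lam(k) ~ N(mu, sigma_lambda^2 I_p), and
symmetric noise eps(k) whose upper triangle (diagonal included) is i.i.d.
N(0, sigma_eps^2).  The model is a curved exponential family; the four
sufficient statistics (mean pattern frame, mean weights, mean squared weight
norm, mean squared residual) determine the closed-form M-step, except for F
whose concentrations require the saddle-point vMF MLE.

Norm convention: a symmetric matrix has n(n+1)/2 free coordinates, and the
noise is generated as independent Gaussians on exactly those (upper triangle
including the diagonal, mirrored below).  All residual norms in the
likelihood, the sufficient statistic S4 and the M-step therefore weight each
unique coordinate once — implemented as a weighted full-matrix sum with
weight 1/2 on off-diagonal entries — and the noise variance is normalized by
the n(n+1)/2 coordinate count.  This keeps the likelihood consistent with
the generative noise (see the methods note for why the superficially simpler
full-matrix n^2 convention is not used).  A data set may additionally carry
a single symmetric boolean mask of observed entries shared by all subjects
(e.g. an unobserved diagonal); masked entries drop out of every norm and of
the coordinate count.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass
from typing import Any

import numpy as np

from . import stiefel, vmf

__all__ = [
    "edge_weights",
    "ModelParams",
    "LatentState",
    "AdjacencyDataset",
    "SufficientStats",
    "reconstruct",
    "sample_dataset",
    "complete_log_likelihood",
    "suff_stats",
    "m_step",
    "diagnostics",
    "uniform_baseline_concentration",
]

_VAR_FLOOR = 1e-12


def edge_weights(n: int, observed: np.ndarray | None = None) -> np.ndarray:
    """Coordinate weights of the symmetric-matrix norm: 1 on the diagonal,
    1/2 on off-diagonal entries (each unordered pair counted once), zero on
    masked entries.  ``sum(edge_weights(n))`` is n(n+1)/2 when unmasked."""
    W = np.full((n, n), 0.5)
    np.fill_diagonal(W, 1.0)
    if observed is not None:
        W = W * observed
    return W


@dataclass
class ModelParams:
    """Parameters (F, mu, sigma_lambda, sigma_eps) of the decomposition model."""

    F: vmf.VMFParam
    mu: np.ndarray
    sigma_lambda: float
    sigma_eps: float

    def __post_init__(self) -> None:
        if not isinstance(self.F, vmf.VMFParam):
            self.F = vmf.VMFParam(np.asarray(self.F, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if self.mu.shape != (self.F.p,):
            raise ValueError(f"mu must have shape ({self.F.p},), got {self.mu.shape}")
        if self.sigma_lambda <= 0 or self.sigma_eps <= 0:
            raise ValueError("sigma_lambda and sigma_eps must be positive")

    @property
    def n(self) -> int:
        return self.F.n

    @property
    def p(self) -> int:
        return self.F.p

    @property
    def mode(self) -> np.ndarray:
        return self.F.mode

    @property
    def concentrations(self) -> np.ndarray:
        return self.F.concentrations

    def degrees_of_freedom(self) -> int:
        """Number of free scalar parameters: n*p + p + 2."""
        return self.n * self.p + self.p + 2

    # -- serialization -----------------------------------------------------

    def save(self, path: str, extra_meta: dict[str, Any] | None = None) -> None:
        """Write a single-archive parameter file (arrays + JSON metadata)."""
        meta = {"n": self.n, "p": self.p}
        if extra_meta:
            meta.update(extra_meta)
        buf = io.BytesIO()
        np.savez(
            buf,
            F=self.F.F,
            mu=self.mu,
            sigma_lambda=self.sigma_lambda,
            sigma_eps=self.sigma_eps,
        )
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("params.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str) -> "ModelParams":
        with zipfile.ZipFile(path) as zf:
            with zf.open("params.npz") as fh:
                arr = np.load(io.BytesIO(fh.read()))
                return cls(
                    F=vmf.VMFParam(arr["F"]),
                    mu=arr["mu"],
                    sigma_lambda=float(arr["sigma_lambda"]),
                    sigma_eps=float(arr["sigma_eps"]),
                )


@dataclass
class LatentState:
    """Per-subject latent variables: pattern frames X and weights lam."""

    X: np.ndarray  # (N, n, p)
    lam: np.ndarray  # (N, p)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.X.ndim != 3 or self.lam.ndim != 2 or self.X.shape[0] != self.lam.shape[0]:
            raise ValueError("inconsistent latent shapes")
        if self.X.shape[2] != self.lam.shape[1]:
            raise ValueError("X and lam disagree on p")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    def copy(self) -> "LatentState":
        return LatentState(self.X.copy(), self.lam.copy())


class AdjacencyDataset:
    """N symmetric n x n matrices plus an optional shared observation mask."""

    def __init__(
        self,
        matrices: np.ndarray,
        observed: np.ndarray | None = None,
        symmetry_tol: float = 1e-9,
    ) -> None:
        A = np.asarray(matrices, dtype=float)
        if A.ndim == 2:
            A = A[None]
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError(f"expected (N, n, n) matrices, got shape {A.shape}")
        asym = np.max(np.abs(A - np.swapaxes(A, 1, 2)))
        if asym > symmetry_tol:
            raise ValueError(f"matrices not symmetric: max asymmetry {asym:.3e}")
        self.matrices = A
        n = A.shape[1]
        if observed is None:
            observed = np.ones((n, n), dtype=bool)
        observed = np.asarray(observed, dtype=bool)
        if observed.shape != (n, n) or not np.array_equal(observed, observed.T):
            raise ValueError("observed mask must be a symmetric (n, n) boolean matrix")
        self.observed = observed

    @property
    def N(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def n_observed(self) -> int:
        """Number of observed entries, full-matrix count (n^2 if unmasked)."""
        return int(np.sum(self.observed))

    @property
    def weights(self) -> np.ndarray:
        """Coordinate weights of the residual norm (see ``edge_weights``)."""
        if not hasattr(self, "_weights"):
            self._weights = edge_weights(self.n_nodes, self.observed)
        return self._weights

    @property
    def weight_total(self) -> float:
        """Number of observed free coordinates, n(n+1)/2 when unmasked."""
        return float(np.sum(self.weights))

    def masked(self) -> np.ndarray:
        """Matrices with unobserved entries zeroed."""
        return self.matrices * self.observed


def reconstruct(X: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Low-rank part ``X Diag(lam) X^T``; supports stacks on both arguments."""
    X = np.asarray(X, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if X.shape[-1] != lam.shape[-1]:
        raise ValueError("X and lam disagree on p")
    return (X * lam[..., None, :]) @ np.swapaxes(X, -1, -2)


def sample_dataset(
    params: ModelParams,
    N: int,
    rng: np.random.Generator,
    n_burnin: int = 600,
    return_noise_free: bool = False,
) -> tuple[AdjacencyDataset, LatentState]:
    """Draw a synthetic data set from the generative model.

    Pattern frames come from the parallel-chain vMF sampler; weights are
    Gaussian; the noise is symmetric with i.i.d. N(0, sigma_eps^2) entries on
    the upper triangle (diagonal included), mirrored below.
    """
    n, p = params.n, params.p
    X = vmf.sample(params.F, N, n_burnin=n_burnin, rng=rng)
    lam = params.mu + params.sigma_lambda * rng.standard_normal((N, p))
    noise = rng.standard_normal((N, n, n)) * params.sigma_eps
    upper = np.triu(noise)
    eps = upper + np.swapaxes(np.triu(noise, k=1), 1, 2)
    low = reconstruct(X, lam)
    A = low + eps
    dataset = AdjacencyDataset(A)
    latents = LatentState(X, lam)
    if return_noise_free:
        return dataset, latents, low
    return dataset, latents


def weighted_sq_norm(R: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    """Squared residual norm; ``weights`` as produced by ``edge_weights``
    (None: plain full-matrix Frobenius)."""
    if weights is None:
        return np.einsum("...ij,...ij->...", R, R)
    return np.einsum("...ij,...ij,ij->...", R, R, weights)


def gaussian_obs_loglik(
    A: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    sigma_eps: float,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Observation term of the complete log-likelihood (per subject):
    independent Gaussians on the observed unique coordinates."""
    n = A.shape[-1]
    W = edge_weights(n, observed)
    R = A - reconstruct(X, lam)
    sq = weighted_sq_norm(R, W)
    count = float(np.sum(W))
    return -0.5 * sq / sigma_eps**2 - count * np.log(
        sigma_eps * np.sqrt(2.0 * np.pi)
    )


def complete_log_likelihood(
    A: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    params: ModelParams,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Complete-data log-likelihood of one subject (or a stack of subjects).

    Sum of the Gaussian observation term (each observed unique coordinate
    counted once), the vMF pattern term tr(F^T X) - log C(F), and the
    Gaussian weight term.
    """
    if params.sigma_eps <= 0 or params.sigma_lambda <= 0:
        raise ValueError("variances must be positive")
    obs = gaussian_obs_loglik(A, X, lam, params.sigma_eps, observed)
    logc = vmf.log_normalizer(params.concentrations, params.n)
    vmf_term = vmf.log_density_unnorm(X, params.F.F) - logc
    p = params.p
    diff = lam - params.mu
    lam_term = -0.5 * np.einsum("...i,...i->...", diff, diff) / params.sigma_lambda**2 \
        - p * np.log(params.sigma_lambda * np.sqrt(2.0 * np.pi))
    return obs + vmf_term + lam_term


def grad_loglik_X(
    A: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    params: ModelParams,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Euclidean gradient of the complete log-likelihood with respect to X."""
    R = (A - reconstruct(X, lam)) * edge_weights(A.shape[-1], observed)
    return 2.0 / params.sigma_eps**2 * np.einsum(
        "...ij,...jk,...k->...ik", R, X, lam
    ) + params.F.F


def grad_loglik_lam(
    A: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    params: ModelParams,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of the complete log-likelihood with respect to lam."""
    R = (A - reconstruct(X, lam)) * edge_weights(A.shape[-1], observed)
    quad = np.einsum("...ik,...ij,...jk->...k", X, R, X)
    return quad / params.sigma_eps**2 - (lam - params.mu) / params.sigma_lambda**2


@dataclass
class SufficientStats:
    """Running averages driving the M-step."""

    s1: np.ndarray  # (n, p): mean of X(k)
    s2: np.ndarray  # (p,): mean of lam(k)
    s3: float  # mean of ||lam(k)||^2
    s4: float  # mean of ||A(k) - lam(k).X(k)||^2 (masked convention)

    def blend(self, other: "SufficientStats", alpha: float) -> "SufficientStats":
        """Stochastic-approximation update (1 - alpha) self + alpha other."""
        return SufficientStats(
            s1=(1.0 - alpha) * self.s1 + alpha * other.s1,
            s2=(1.0 - alpha) * self.s2 + alpha * other.s2,
            s3=(1.0 - alpha) * self.s3 + alpha * other.s3,
            s4=(1.0 - alpha) * self.s4 + alpha * other.s4,
        )


def suff_stats(dataset: AdjacencyDataset, latents: LatentState) -> SufficientStats:
    """Sufficient statistics of the complete likelihood, averaged over subjects."""
    if latents.N != dataset.N:
        raise ValueError("dataset and latents disagree on N")
    R = dataset.matrices - reconstruct(latents.X, latents.lam)
    sq = weighted_sq_norm(R, dataset.weights)
    return SufficientStats(
        s1=np.mean(latents.X, axis=0),
        s2=np.mean(latents.lam, axis=0),
        s3=float(np.mean(np.sum(latents.lam**2, axis=1))),
        s4=float(np.mean(sq)),
    )


def m_step(
    S: SufficientStats,
    n: int,
    p: int,
    obs_weight: float | None = None,
    prev: ModelParams | None = None,
) -> ModelParams:
    """Closed-form M-step; F via the constrained saddle-point vMF MLE.

    ``obs_weight`` is the observed coordinate count per matrix (defaults to
    n(n+1)/2, fully observed); ``prev`` warm-starts the concentration solve
    from the previous parameter values.
    """
    if obs_weight is None:
        obs_weight = n * (n + 1) / 2.0
    mu = np.asarray(S.s2, dtype=float)
    var_lam = (S.s3 - 2.0 * float(np.dot(mu, S.s2)) + float(np.dot(mu, mu))) / p
    var_eps = S.s4 / obs_weight
    if var_lam < _VAR_FLOOR:
        if var_lam < -1e-8:
            warnings.warn(
                f"negative weight-variance estimate {var_lam:.3e} clipped "
                "(finite-sample artifact)",
                RuntimeWarning,
            )
        var_lam = _VAR_FLOOR
    if var_eps < _VAR_FLOOR:
        var_eps = _VAR_FLOOR
    s0 = None if prev is None else np.sort(prev.concentrations)[::-1]
    F = vmf.mle_from_mean(S.s1, orthogonal_columns=True, s0=s0)
    return ModelParams(
        F=F,
        mu=mu,
        sigma_lambda=float(np.sqrt(var_lam)),
        sigma_eps=float(np.sqrt(var_eps)),
    )


def uniform_baseline_concentration(
    n: int,
    p: int,
    N: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Concentrations the vMF MLE reports on pure Haar-uniform frames.

    Draws N uniform frames, aligns them all to the first with the greedy
    column matching used during fitting, and runs the constrained MLE on
    their mean.  Serves as the no-structure reference level against which
    fitted concentration parameters are judged.
    """
    from .saem import greedy_column_match  # local import to avoid a cycle

    X = stiefel.sample_uniform(n, p, rng, size=N)
    ref = X[0]
    for k in range(1, N):
        _, _, X[k] = greedy_column_match(X[k], ref)
    return vmf.mle_from_mean(np.mean(X, axis=0)).concentrations


def diagnostics(
    dataset: AdjacencyDataset,
    latents: LatentState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    baseline_samples: int = 0,
) -> dict[str, Any]:
    """Fit-quality report: reconstruction errors, variance explained,
    concentrations (optionally with the uniform-baseline reference).

    Relative errors use the masked Frobenius norm; the spread reported is the
    standard deviation across the adjacency matrices.
    """
    A = dataset.matrices * dataset.observed
    low = reconstruct(latents.X, latents.lam) * dataset.observed
    res_sq = np.einsum("kij,kij->k", A - low, A - low)
    norm_sq = np.einsum("kij,kij->k", A, A)
    rel = np.sqrt(res_sq / np.maximum(norm_sq, 1e-300))
    total = float(np.sum(norm_sq))
    var_explained = 1.0 - float(np.sum(res_sq)) / total if total > 0 else 0.0
    report: dict[str, Any] = {
        "relative_error_mean": float(np.mean(rel)),
        "relative_error_std": float(np.std(rel)),
        "variance_explained": var_explained,
        "concentrations": params.concentrations.tolist(),
        "degrees_of_freedom": params.degrees_of_freedom(),
    }
    if baseline_samples > 0:
        if rng is None:
            rng = np.random.default_rng()
        base = uniform_baseline_concentration(
            params.n, params.p, baseline_samples, rng
        )
        report["uniform_baseline_concentrations"] = base.tolist()
    return report
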