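"""Matrix von Mises--Fisher (matrix Langevin) distributions on V(n, p).

The density with parameter ``F`` (an ``n x p`` real matrix) is

    p(X) = exp(tr(F^T X)) / C(F)

with respect to the *normalized* invariant (Haar) measure on the Stiefel
manifold, so that ``C(0) = 1``.  When the columns of ``F`` are orthogonal
(the only case used by the network model) the column norms of ``F`` are its
singular values; they act as concentration parameters and ``project(F)`` is
the mode of the distribution.

The normalizing constant is a hypergeometric function of matrix argument
and is intractable exactly.  ``log_normalizer`` implements a saddle-point
approximation: ``C(F)`` equals, up to the factor ``exp(||F||^2/2)``, a ratio
of values of the density of a noncentral Wishart matrix ``W = Z^T Z`` at the
identity (``Z`` columnwise Gaussian around the columns of ``F``).  The
cumulant generating function of ``W`` is available in closed form and, for
diagonal noncentrality, the saddle point solves a scalar quadratic per
coordinate.  The standard second-order correction (the rho_4, rho_13^2,
rho_23^2 invariants, applied in exponential form) is included.

Maximum-likelihood estimation of ``F`` from a sample mean follows the
classical SVD reduction: the mode is the polar factor of the mean, and the
concentrations solve a p-dimensional concave problem involving the
log-normalizer, solved numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .stiefel import project_to_stiefel, propose_move, sample_uniform

__all__ = [
    "VMFParam",
    "log_density_unnorm",
    "log_normalizer",
    "mle_from_mean",
    "sample",
]

#: Tolerance on pairwise column orthogonality of F (model constraint).
COLUMN_ORTHOGONALITY_TOL = 1e-6


@dataclass
class VMFParam:
    """Parameter of a matrix von Mises--Fisher distribution.

    The model constrains the columns of ``F`` to be pairwise orthogonal, in
    which case the column norms coincide with the singular values of ``F``
    and are the concentration parameters of the distribution.
    """

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[1] > self.F.shape[0]:
            raise ValueError(f"F must be (n, p) with p <= n, got {self.F.shape}")
        gram = self.F.T @ self.F
        off = gram - np.diag(np.diag(gram))
        scale = max(1.0, float(np.max(np.abs(gram))))
        if np.max(np.abs(off)) > COLUMN_ORTHOGONALITY_TOL * scale:
            raise ValueError(
                "columns of F are not pairwise orthogonal within tolerance"
            )

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def p(self) -> int:
        return self.F.shape[1]

    @property
    def concentrations(self) -> np.ndarray:
        """Column norms of F (the concentration parameters)."""
        return np.linalg.norm(self.F, axis=0)

    @property
    def mode(self) -> np.ndarray:
        """The manifold point of maximal density, project(F)."""
        return project_to_stiefel(self.F)


def log_density_unnorm(X: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Unnormalized log-density ``tr(F^T X)``; broadcasts over stacks of X."""
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if X.shape[-2:] != F.shape:
        raise ValueError(f"shape mismatch: X {X.shape[-2:]} vs F {F.shape}")
    return np.einsum("...ij,ij->...", X, F)


# ---------------------------------------------------------------------------
# Saddle-point log-normalizer
# ---------------------------------------------------------------------------


def _spa_terms(delta: np.ndarray, n: int) -> tuple[float, float]:
    """Log saddle-point density of W = Z'Z at I_p (up to the 2*pi factor,
    which cancels in the normalizer ratio) and its second-order correction.

    ``delta`` holds the noncentrality eigenvalues (squared concentrations).
    The saddle point in the coordinate u_i = 1 - 2*t_i solves
    u^2 - n*u - delta_i = 0.
    """
    p = delta.size
    u = 0.5 * (n + np.sqrt(n * n + 4.0 * delta))
    g = 1.0 / u
    a = g * delta

    # K(T_hat) - tr(T_hat)
    base = -0.5 * n * np.sum(np.log(u)) + 0.5 * np.sum(delta * (g - 1.0)) \
        - 0.5 * np.sum(1.0 - u)

    # Hessian of the CGF at the saddle point, diagonal in the natural basis
    # of symmetric matrices: one entry per diagonal coordinate, one per
    # off-diagonal pair.
    hD = 2.0 * g * g * (n + 2.0 * a)
    gi, gj = g[:, None], g[None, :]
    ai, aj = a[:, None], a[None, :]
    hO = 4.0 * gi * gj * (n + ai + aj)
    iu = np.triu_indices(p, k=1)
    logdet = np.sum(np.log(hD)) + np.sum(np.log(hO[iu]))
    L = base - 0.5 * logdet

    # --- second-order invariants -----------------------------------------
    # Third cumulants: closed walks visiting one, two or three nodes.
    c_iii = 8.0 * g**3 * (n + 3.0 * a)
    c_ioo = 8.0 * gi * gi * gj * (n + 2.0 * ai + aj)  # (D_i, O_ij, O_ij)

    # Fourth cumulants contracted pairwise.
    q_iiii = 48.0 * g**4 * (n + 4.0 * a)
    q_iioo = 32.0 * gi**3 * gj * (n + 3.0 * ai + aj)  # (D_i D_i, O_ij O_ij)
    q_oooo = 96.0 * gi**2 * gj**2 * (n + 2.0 * ai + 2.0 * aj)  # O_ij with itself

    offmask = ~np.eye(p, dtype=bool)

    rho4 = float(np.sum(q_iiii / hD**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(offmask, q_iioo / (hD[:, None] * hO), 0.0)
    rho4 += 2.0 * float(np.sum(t2))
    rho4 += float(np.sum((q_oooo / hO**2)[iu]))

    # nu_a = sum_b kappa_{abb}/h_b is nonzero only for diagonal coordinates.
    with np.errstate(divide="ignore", invalid="ignore"):
        nu_off = np.where(offmask, c_ioo / hO, 0.0)
    nu = c_iii / hD + np.sum(nu_off, axis=1)
    rho13 = float(np.sum(nu * nu / hD))

    rho23 = float(np.sum(c_iii**2 / hD**3))
    with np.errstate(divide="ignore", invalid="ignore"):
        t23 = np.where(offmask, c_ioo**2 / (hD[:, None] * hO**2), 0.0)
    rho23 += 3.0 * float(np.sum(t23))

    if p >= 3:
        # Triples of distinct indices i<j<k: walks through three nodes and
        # pairs of off-diagonal coordinates sharing one node.
        distinct, share = _triple_masks(p)
        gg = gi * gj
        aa = ai + aj
        c3 = 8.0 * gg[:, :, None] * g[None, None, :] * (
            n + aa[:, :, None] + a[None, None, :]
        )  # c_ooo[i,j,k]
        hOij = hO[:, :, None]
        hOjk = hO.T[None, :, :]  # hO[j,k] broadcast as [., j, k]
        hOik = hO[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            tri = np.where(distinct, c3**2 / (hOij * hOjk * hOik), 0.0)
        rho23 += 6.0 * float(np.sum(tri))

        # rho4 contribution of pairs (O_ij, O_jk) sharing node j (i<k).
        q_shared = 32.0 * g[None, :, None] ** 2 * g[:, None, None] * g[
            None, None, :
        ] * (
            n
            + a[:, None, None]
            + 2.0 * a[None, :, None]
            + a[None, None, :]
        )  # indexed [i, j, k]
        hO_ij_ = hO.T[:, :, None]  # hO[i,j] as [i,j,.]
        hO_jk_ = hO[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            t4s = np.where(share, q_shared / (hO_ij_ * hO_jk_), 0.0)
        rho4 += 2.0 * float(np.sum(t4s))

    corr = rho4 / 8.0 - (3.0 * rho13 + 2.0 * rho23) / 24.0
    return float(L), float(corr)


_TRIPLE_MASK_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_ZERO_TERM_CACHE: dict[tuple[int, int], tuple[float, float]] = {}


def _triple_masks(p: int) -> tuple[np.ndarray, np.ndarray]:
    if p not in _TRIPLE_MASK_CACHE:
        idx = np.arange(p)
        i_idx = idx[:, None, None]
        j_idx = idx[None, :, None]
        k_idx = idx[None, None, :]
        distinct = (i_idx < j_idx) & (j_idx < k_idx)
        share = (i_idx < k_idx) & (i_idx != j_idx) & (k_idx != j_idx)
        _TRIPLE_MASK_CACHE[p] = (distinct, share)
    return _TRIPLE_MASK_CACHE[p]


def _spa_terms_zero(p: int, n: int) -> tuple[float, float]:
    key = (p, n)
    if key not in _ZERO_TERM_CACHE:
        _ZERO_TERM_CACHE[key] = _spa_terms(np.zeros(p), n)
    return _ZERO_TERM_CACHE[key]


def log_normalizer(s: np.ndarray | float, n: int, order: int = 2) -> float:
    """Approximate ``log C(F)`` for ``F`` with singular values ``s`` on V(n, p).

    Normalized against the Haar probability measure, so ``s = 0`` gives 0.
    ``order=1`` drops the second-order correction factor (exposed for
    diagnostics; the default includes it).
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if s.ndim != 1:
        raise ValueError("s must be a vector of singular values")
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise ValueError(f"singular values must be finite and >= 0, got {s}")
    p = s.size
    if n < p:
        raise ValueError(f"need n >= p, got n={n}, p={p}")
    delta = s * s
    L1, c1 = _spa_terms(delta, n)
    L0, c0 = _spa_terms_zero(p, n)
    if order == 1:
        c1 = c0 = 0.0
    out = (L1 + c1) - (L0 + c0) + 0.5 * float(np.sum(delta))
    if not np.isfinite(out):
        raise FloatingPointError(
            f"saddle-point log-normalizer failed for s={s}, n={n}"
        )
    return out


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


def _mle_concentrations(
    dbar: np.ndarray, n: int, s0: np.ndarray | None = None
) -> np.ndarray:
    """Solve max_s sum(s * dbar) - log C(s) over s >= 0.

    ``dbar`` are the 'resultant' coefficients in (0, 1); the objective is the
    profile log-likelihood of the concentrations, concave because log C is an
    exponential-family log-partition in s.  Initialized from the classical
    high-concentration approximation s ~ n*d/(1-d^2).
    """
    dbar = np.asarray(dbar, dtype=float)
    p = dbar.size
    if s0 is None:
        with np.errstate(divide="ignore"):
            s0 = n * dbar / np.maximum(1.0 - dbar**2, 1e-12)
    s0 = np.clip(np.asarray(s0, dtype=float), 1e-3, 1e4)

    def negobj(s: np.ndarray) -> float:
        return -(float(np.dot(s, dbar)) - log_normalizer(s, n))

    res = optimize.minimize(
        negobj,
        s0,
        method="L-BFGS-B",
        bounds=[(0.0, 1e6)] * p,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    if not res.success and not np.all(np.isfinite(res.x)):
        raise RuntimeError(
            f"concentration MLE did not converge: {res.message}; last iterate {res.x}"
        )
    return np.asarray(res.x, dtype=float)


def mle_from_mean(
    Xbar: np.ndarray,
    orthogonal_columns: bool = True,
    s0: np.ndarray | None = None,
) -> VMFParam:
    """Maximum-likelihood vMF parameter from the arithmetic mean of samples.

    With ``orthogonal_columns`` (the network model's constraint) the estimate
    is ``M Diag(s)`` with ``M`` the polar factor of ``Xbar`` and ``s``
    maximizing ``tr(Diag(s) M^T Xbar) - log C(s)``.  Without the constraint
    the classical unconstrained form ``U Diag(s) V^T`` is used, with the same
    scalar problem driven by the singular values of ``Xbar``; that branch
    exists for cross-checks against the directional-statistics literature.
    """
    Xbar = np.asarray(Xbar, dtype=float)
    n, p = Xbar.shape
    U, d, Vt = np.linalg.svd(Xbar, full_matrices=False)
    if np.min(d) <= 1e-12:
        raise ValueError("rank-deficient sample mean; vMF MLE undefined")
    if orthogonal_columns:
        M = U @ Vt
        dbar = np.diag(M.T @ Xbar).copy()
        s = _mle_concentrations(dbar, n, s0)
        return VMFParam(M @ np.diag(s))
    s = _mle_concentrations(d, n, s0)
    return VMFParam(U @ np.diag(s) @ Vt)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample(
    F: np.ndarray | VMFParam,
    n_samples: int,
    n_burnin: int = 600,
    rng: np.random.Generator | None = None,
    target_accept: float = 0.3,
    initial_step: float = 0.1,
    adapt_every: int = 20,
) -> np.ndarray:
    """Draw ``n_samples`` (approximately independent) vMF samples.

    Runs ``n_samples`` Metropolis--Hastings chains in parallel, each using
    the projected Gaussian random-walk proposal, for ``n_burnin`` steps, and
    returns the final state of each chain.  The proposal step size is shared
    across chains and adapted on the log scale toward ``target_accept``
    using the pooled acceptance fraction.  Chains start at the mode (or at
    uniform draws when ``F = 0``), which is unbiased by symmetry of the
    target around its mode.
    """
    if rng is None:
        rng = np.random.default_rng()
    Fm = F.F if isinstance(F, VMFParam) else np.asarray(F, dtype=float)
    n, p = Fm.shape
    if np.allclose(Fm, 0.0):
        start = sample_uniform(n, p, rng, size=n_samples)
    else:
        start = np.broadcast_to(project_to_stiefel(Fm), (n_samples, n, p)).copy()
    X = start
    logp = np.einsum("kij,ij->k", X, Fm)
    log_step = np.log(initial_step)
    n_acc = 0
    n_tot = 0
    adapt_count = 0
    for it in range(n_burnin):
        prop = propose_move(X, float(np.exp(log_step)), rng)
        logp_prop = np.einsum("kij,ij->k", prop, Fm)
        accept = np.log(rng.random(n_samples)) < (logp_prop - logp)
        X[accept] = prop[accept]
        logp[accept] = logp_prop[accept]
        n_acc += int(np.sum(accept))
        n_tot += n_samples
        if (it + 1) % adapt_every == 0:
            adapt_count += 1
            ell = 1.0 if (n_acc / n_tot) > target_accept else -1.0
            log_step += ell / (2.0 * adapt_count**0.6)
            n_acc = n_tot = 0
    return X
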