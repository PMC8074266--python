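"""Geometry of the compact Stiefel manifold V(n, p).

V(n, p) is the set of n x p real matrices with orthonormal columns.  This
module provides the handful of geometric primitives the rest of the package
builds on: SVD-based projection (which is also the retraction used
everywhere), Haar-uniform sampling, Gaussian random-walk proposals for
Metropolis--Hastings, and a projected gradient-ascent step.

Geodesic and Cayley-transform proposals are deliberately not implemented:
the projection proposal performs equivalently in practice and is the
cheapest of the three.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ORTHONORMALITY_TOL",
    "is_on_stiefel",
    "check_stiefel",
    "project_to_stiefel",
    "sample_uniform",
    "propose_move",
    "tangent_project",
    "riemannian_ascent_step",
]

#: Tolerance on ||X^T X - I||_inf for manifold membership checks.
ORTHONORMALITY_TOL = 1e-8

_RANK_TOL = 1e-12


def is_on_stiefel(X: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> bool:
    """Return True if every frame in ``X`` has orthonormal columns.

    ``X`` may be a single ``(n, p)`` matrix or a stack ``(..., n, p)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim < 2 or X.shape[-1] > X.shape[-2]:
        return False
    p = X.shape[-1]
    gram = np.swapaxes(X, -1, -2) @ X
    return bool(np.max(np.abs(gram - np.eye(p))) <= tol)


def check_stiefel(X: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> np.ndarray:
    """Validate that ``X`` lies on the Stiefel manifold and return it."""
    X = np.asarray(X, dtype=float)
    if not is_on_stiefel(X, tol):
        raise ValueError(
            "matrix is not on the Stiefel manifold within tolerance "
            f"{tol:g} (shape {X.shape})"
        )
    return X


def _fix_svd_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Fix the sign of each left singular vector so that its largest-magnitude
    # entry is positive; the compensating sign goes into Vt.  The product
    # U @ Vt is unchanged; this only pins down the (U, Vt) pair across
    # LAPACK implementations.
    idx = np.argmax(np.abs(U), axis=-2)
    taken = np.take_along_axis(U, idx[..., None, :], axis=-2)[..., 0, :]
    signs = np.where(taken >= 0, 1.0, -1.0)
    return U * signs[..., None, :], Vt * signs[..., :, None]


def project_to_stiefel(M: np.ndarray) -> np.ndarray:
    """Orthogonal projection of ``M`` onto V(n, p).

    For a full-column-rank matrix with thin SVD ``M = U D V^T`` the unique
    Frobenius-nearest point with orthonormal columns is ``U V^T``.  Works on
    stacks ``(..., n, p)``.

    Raises
    ------
    ValueError
        If any matrix in the stack is (numerically) rank deficient, in which
        case the projection is not unique.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim < 2 or M.shape[-1] > M.shape[-2]:
        raise ValueError(f"expected shape (..., n, p) with p <= n, got {M.shape}")
    U, d, Vt = np.linalg.svd(M, full_matrices=False)
    if np.min(d) <= _RANK_TOL:
        raise ValueError(
            "rank-deficient input: smallest singular value "
            f"{np.min(d):.3e} <= {_RANK_TOL:g}; projection onto the Stiefel "
            "manifold is not unique"
        )
    U, Vt = _fix_svd_signs(U, Vt)
    return U @ Vt


def sample_uniform(
    n: int, p: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Haar-uniform draw(s) from V(n, p).

    Orthonormalizes a standard Gaussian matrix by QR with the sign convention
    that the triangular factor has a positive diagonal, which makes the
    result exactly Haar distributed.

    Returns a single ``(n, p)`` frame, or a stack ``(size, n, p)``.
    """
    if not (1 <= p <= n):
        raise ValueError(f"need 1 <= p <= n, got n={n}, p={p}")
    shape = (n, p) if size is None else (size, n, p)
    Z = rng.standard_normal(shape)
    Q, R = np.linalg.qr(Z)
    diag = np.diagonal(R, axis1=-2, axis2=-1)
    signs = np.where(diag >= 0, 1.0, -1.0)
    return Q * signs[..., None, :]


def propose_move(
    X: np.ndarray, step: float, rng: np.random.Generator, max_retries: int = 5
) -> np.ndarray:
    """Gaussian random-walk proposal projected back onto the manifold.

    Returns ``project(X + step * Z)`` with ``Z`` standard Gaussian.  On the
    (measure-zero) event that the perturbed matrix is rank deficient, a fresh
    ``Z`` is drawn, up to ``max_retries`` times.  Supports stacks.
    """
    X = np.asarray(X, dtype=float)
    if step == 0.0:
        return X.copy()
    for _ in range(max_retries):
        try:
            return project_to_stiefel(X + step * rng.standard_normal(X.shape))
        except ValueError:
            continue
    raise RuntimeError("propose_move: repeated rank-deficient proposals")


def tangent_project(X: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Project an ambient gradient ``G`` onto the tangent space at ``X``.

    Uses the projection associated with the embedded metric:
    ``G - X sym(X^T G)`` with ``sym(A) = (A + A^T)/2``.  Supports stacks.
    """
    XtG = np.swapaxes(X, -1, -2) @ G
    sym = 0.5 * (XtG + np.swapaxes(XtG, -1, -2))
    return G - X @ sym


def riemannian_ascent_step(
    X: np.ndarray, euclidean_grad: np.ndarray, step: float
) -> np.ndarray:
    """One projected gradient-ascent step on the Stiefel manifold.

    Moves ``X`` along the tangent projection of ``euclidean_grad`` and
    retracts with the SVD projection.  Step-size control (backtracking so the
    objective does not decrease) is the caller's responsibility.
    """
    G = np.asarray(euclidean_grad, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite gradient passed to riemannian_ascent_step")
    xi = tangent_project(np.asarray(X, dtype=float), G)
    return project_to_stiefel(X + step * xi)
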