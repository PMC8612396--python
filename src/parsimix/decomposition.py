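"""Volume/shape/rotation decomposition of covariance matrices.

Every symmetric positive-definite ``Sigma`` factors as
``Sigma = d * R @ diag(D) @ R.T`` with ``d = det(Sigma)**(1/p)`` (the volume),
``D`` a positive vector with unit product (the shape) and ``R`` orthogonal
(the rotation).  Shapes are carried around as 1-D vectors of the diagonal.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidDecompositionError, SingularCovarianceError


def compose_scatter(d: float, D: np.ndarray, R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Compose ``d * R @ diag(D) @ R.T`` from a valid decomposition triple.

    ``D`` may be given as a diagonal matrix or as the vector of its diagonal;
    it must have unit product, and ``R`` must be orthogonal, both up to
    ``tol``.  The determinant of the result equals ``d**p``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim == 2:
        if not np.allclose(D, np.diag(np.diag(D))):
            raise InvalidDecompositionError("shape matrix D is not diagonal")
        D = np.diag(D)
    R = np.asarray(R, dtype=float)
    p = D.shape[0]
    if d <= 0:
        raise InvalidDecompositionError(f"volume d must be positive, got {d}")
    if np.any(D <= 0):
        raise InvalidDecompositionError("shape elements must be positive")
    if abs(np.prod(D) - 1.0) > tol * p:
        raise InvalidDecompositionError(
            f"shape matrix must have unit determinant, got {np.prod(D)}"
        )
    if np.linalg.norm(R.T @ R - np.eye(p)) > tol * p:
        raise InvalidDecompositionError("R is not orthogonal within tolerance")
    return d * (R * D) @ R.T


def _canonicalize_signs(R: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the first non-negligible entry is positive."""
    R = R.copy()
    for col in range(R.shape[1]):
        v = R[:, col]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            R[:, col] = -v
    return R


def decompose_scatter(Sigma: np.ndarray, rotation: str = "V", tol: float = 1e-10):
    """Decompose an SPD matrix into its (volume, shape, rotation) triple.

    Returns ``(d, D, R)`` with ``d = det(Sigma)**(1/p)``, ``D`` the unit-product
    shape vector and ``R`` orthogonal, such that ``compose_scatter`` recovers
    ``Sigma``.  Under the free-rotation regime (``rotation="V"``) the shape
    elements are returned in non-increasing order by permuting eigenpairs;
    eigenvector signs are canonicalized for determinism.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    p = Sigma.shape[0]
    if Sigma.shape != (p, p) or not np.allclose(Sigma, Sigma.T, atol=1e-8 * (1 + np.abs(Sigma).max())):
        raise SingularCovarianceError("input matrix is not symmetric")
    evals, evecs = np.linalg.eigh(Sigma)
    if evals[0] <= tol * max(abs(evals[-1]), 1.0) or evals[0] <= 0:
        raise SingularCovarianceError(
            f"matrix is not positive definite (min eigenvalue {evals[0]:.3e})"
        )
    # reorder eigenpairs to non-increasing eigenvalues; a stable sort keeps
    # tied eigenpairs in their original order (so spherical matrices keep
    # the identity rotation)
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    d = float(np.exp(np.mean(np.log(evals))))
    D = evals / d
    R = _canonicalize_signs(evecs)
    return d, D, R


def compose_batch(d: np.ndarray, D: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Compose k covariances from batched triples (no validation).

    ``d``: (k,), ``D``: (k, p) shape vectors, ``R``: (k, p, p).
    """
    return d[:, None, None] * np.einsum("kij,kj,klj->kil", R, D, R)
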