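"""Constrained Gaussian mixture fitting via a nested ECM algorithm.

The estimator maximizes either the mixture log-likelihood (EM) or the
classification log-likelihood (CEM, hard assignments) over mixture
parameters whose component covariances obey the determinant-ratio,
shape-within and shape-between constraints of a :class:`ConstraintSpec`
plus a rotation regime.  Each outer iteration performs

1. an E-step (soft responsibilities or hard assignments),
2. closed-form weight and mean updates,
3. a constrained scatter update that cycles shape / volume / rotation
   conditional maximizations, each imposed through the weighted optimal
   truncation operator, until the decomposition stabilizes.

Multiple random starts are run from independent seeded substreams and the
best target value is returned.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import _ecm_fast
from .constraints import ConstraintSpec, check_constraints
from .decomposition import _canonicalize_signs, compose_batch
from .exceptions import (
    DegenerateScatterError,
    DegenerateStartError,
    FitFailureError,
)
from .likelihood import classification_loglik, mixture_loglik, weighted_log_densities
from .params import MixtureParameters
from .truncation import opt_trunc, opt_trunc_batch

logger = logging.getLogger(__name__)

_TINY = 1e-300


# ---------------------------------------------------------------------------
# convergence monitors
# ---------------------------------------------------------------------------

def relative_change(prev, curr) -> float:
    """Maximal per-component relative change between two parameter iterates.

    Arrays are interpreted with the first axis indexing components; each
    component block is vectorized and the change is ``||curr_j - prev_j|| /
    ||prev_j||``, maximized over components.  A zero-norm previous block with
    a nonzero update is reported as ``inf`` (forcing a further iteration).
    """
    prev = np.atleast_1d(np.asarray(prev, dtype=float))
    curr = np.atleast_1d(np.asarray(curr, dtype=float))
    if prev.shape != curr.shape:
        raise ValueError("parameter shapes do not agree")
    k = prev.shape[0]
    pv = prev.reshape(k, -1)
    cv = curr.reshape(k, -1)
    base = np.linalg.norm(pv, axis=1)
    diff = np.linalg.norm(cv - pv, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(base > 0, diff / base, np.where(diff > 0, np.inf, 0.0))
    return float(rel.max())


def rotation_change(R_prev: np.ndarray, R_curr: np.ndarray) -> float:
    """Relative-change monitor for orthogonal iterates.

    ``|p - trace[((R' R_prev)') (R R_prev')]| / p``, which is zero when the
    two rotations coincide.
    """
    p = R_prev.shape[0]
    A = (R_curr.T @ R_prev).T
    B = R_curr @ R_prev.T
    return float(abs(p - np.trace(A @ B)) / p)


# ---------------------------------------------------------------------------
# ECM building blocks
# ---------------------------------------------------------------------------

def initialize_parameters(X: np.ndarray, k: int, rng: np.random.Generator) -> MixtureParameters:
    """Random initialization from k(p+1) observations.

    Draws ``k * (p + 1)`` observations without replacement, splits them into
    ``k`` groups of ``p + 1`` and uses each group's sample mean and covariance
    as the initial component; weights start uniform.  The constraints need not
    hold at this point -- they are imposed by the first scatter update.  When
    ``n < k(p+1)`` the draw falls back to sampling with replacement, and
    singular group covariances receive a small diagonal ridge.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    need = k * (p + 1)
    if n >= need:
        idx = rng.choice(n, size=need, replace=False)
    else:
        logger.warning(
            "n=%d < k(p+1)=%d observations; initializing with replacement", n, need
        )
        idx = rng.choice(n, size=need, replace=True)
    groups = idx.reshape(k, p + 1)
    means = np.empty((k, p))
    covs = np.empty((k, p, p))
    for j in range(k):
        G = X[groups[j]]
        means[j] = G.mean(axis=0)
        C = (G - means[j]).T @ (G - means[j]) / (p + 1)
        evals = np.linalg.eigvalsh(C)
        if evals[0] <= 1e-10 * max(evals[-1], 1.0):
            ridge = 1e-6 * max(np.trace(C) / p, 1.0)
            C = C + ridge * np.eye(p)
            logger.debug("ridge %g applied to singular initial scatter %d", ridge, j)
        covs[j] = C
    weights = np.full(k, 1.0 / k)
    return MixtureParameters(weights=weights, means=means, covariances=covs)


def e_step(X: np.ndarray, params: MixtureParameters, mode: str = "em"):
    """Observation weights given current parameters.

    Returns ``(tau, log_weighted)`` where ``tau`` is (n, k): posterior
    responsibilities for EM, one-hot hard assignments (ties to the lowest
    component index) for CEM.  Densities are evaluated in log space so rows
    always normalize.
    """
    lw = weighted_log_densities(X, params)
    if mode == "cem":
        labels = np.argmax(lw, axis=1)
        tau = np.zeros_like(lw)
        tau[np.arange(lw.shape[0]), labels] = 1.0
    elif mode == "em":
        tau = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    else:
        raise ValueError(f"mode must be 'em' or 'cem', got {mode!r}")
    return tau, lw


def m_step_weights_means(X: np.ndarray, tau: np.ndarray):
    """Closed-form updates of weights, means and weighted scatter matrices.

    Returns ``(pi, mu, n_j, S_j)`` with ``S_j`` the responsibility-weighted
    covariance about the updated mean (denominator ``n_j``).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    nj = tau.sum(axis=0)
    pi = nj / n
    mu = (tau.T @ X) / np.maximum(nj, _TINY)[:, None]
    diff = X[None, :, :] - mu[:, None, :]  # (k, n, p)
    S = np.einsum("kn,kni,knj->kij", tau.T, diff, diff) / np.maximum(nj, _TINY)[:, None, None]
    return pi, mu, nj, S


def _eigh_descending(M: np.ndarray):
    """Batched symmetric eigendecomposition, eigenvalues non-increasing."""
    evals, evecs = np.linalg.eigh(M)
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    return evals, evecs


def _shape_base(S: np.ndarray, nj: np.ndarray, d: np.ndarray, R: np.ndarray, rotation: str) -> np.ndarray:
    """Unconstrained conditional shape maximizer diag(R_j' S_j R_j) / d_j."""
    if rotation == "I":
        base = np.diagonal(S, axis1=1, axis2=2).copy()
    else:
        base = np.einsum("kai,kab,kbi->ki", R, S, R)
    return base / d[:, None]


def update_shapes(
    S: np.ndarray,
    nj: np.ndarray,
    d: np.ndarray,
    R: np.ndarray,
    spec: ConstraintSpec,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> np.ndarray:
    """Constrained update of the unit-determinant shape vectors.

    Starting from the unconstrained conditional maximizer, iterates:
    shape-within truncation (unit weights, per component), sorting under the
    free-rotation regime, shape-between truncation (weights ``n_j``, per
    coordinate), unsorting, determinant normalization -- until the iterate
    stabilizes.  Normalizing after the truncations makes the between step
    act on the raw conditional maximizers, whose truncation objective is the
    exact conditional likelihood; the limit cases then reproduce the
    classical pooled/per-component shape estimators exactly.  Returns a
    (k, p) array of unit-determinant shape vectors satisfying the
    within/between ratio constraints (exactly at a fixed point, to the loop
    tolerance otherwise).
    """
    k, p = S.shape[0], S.shape[1]
    if spec.c_shw == 1:
        return np.ones((k, p))
    base = _shape_base(S, nj, d, R, spec.rotation)
    if math.isinf(spec.c_shw) and math.isinf(spec.c_shb):
        # unconstrained shapes: floor vanished elements, normalize
        rowmax = base.max(axis=1)
        if np.any(rowmax <= 0):
            raise DegenerateScatterError(
                f"collapsed shape in components {np.flatnonzero(rowmax <= 0)}"
            )
        base = np.maximum(base, 1e-12 * rowmax[:, None])
        return base / np.exp(np.mean(np.log(base), axis=1))[:, None]
    D_prev = base
    for _ in range(max_iter):
        E = opt_trunc_batch(np.ones(p), D_prev, spec.c_shw)
        if spec.rotation == "V":
            order = np.argsort(-E, axis=1, kind="stable")
            Es = np.take_along_axis(E, order, axis=1)
        else:
            order = None
            Es = E
        Et = opt_trunc_batch(nj, Es.T, spec.c_shb).T
        if order is not None:
            E_new = np.empty_like(Et)
            np.put_along_axis(E_new, order, Et, axis=1)
        else:
            E_new = Et
        E_new = E_new / np.exp(np.mean(np.log(E_new), axis=1))[:, None]
        delta = relative_change(D_prev, E_new)
        D_prev = E_new
        if delta <= tol:
            break
    return D_prev


def update_volumes(
    S: np.ndarray,
    nj: np.ndarray,
    D: np.ndarray,
    R: np.ndarray,
    c_det: float,
) -> np.ndarray:
    """Constrained update of the volume parameters.

    Computes the conditional volume proxies ``nu_j = trace(D_j^{-1} R_j' S_j
    R_j) / p`` and truncates them with weights ``n_j`` at ``c_det**(1/p)``, so
    the resulting determinant ratio respects ``c_det``.
    """
    p = S.shape[1]
    quad = np.einsum("kai,kab,kbi->ki", R, S, R)
    nu = np.sum(quad / D, axis=1) / p
    if math.isinf(c_det):
        if np.all(nu <= 0):
            raise DegenerateScatterError("all volume proxies are zero")
        return np.maximum(nu, 1e-12 * nu.max())
    return opt_trunc(nj, nu, c_det ** (1.0 / p))


def update_rotation_common(
    S: np.ndarray,
    nj: np.ndarray,
    d: np.ndarray,
    D: np.ndarray,
    R_init: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-6,
):
    """Majorization update of the common rotation (rot="E" regime).

    Minimizes the complete-data trace objective ``sum_j tr(A_j R' W_j R)``
    with ``W_j = (n_j/n) S_j`` and ``A_j = d_j^{-1} D_j^{-1}`` over orthogonal
    ``R`` by iterating the linear majorization step: with ``omega_j`` the
    largest eigenvalue of ``W_j``, maximize ``<R, G>`` for ``G = sum_j
    (omega_j I - W_j) R^(r-1) A_j`` via the singular value decomposition
    ``G = U Sigma V'`` and set ``R^(r) = U V'``.  Each accepted iterate does
    not decrease the complete-data target.  Returns ``(R, converged)``.
    """
    k, p = S.shape[0], S.shape[1]
    n = nj.sum()
    W = (nj / n)[:, None, None] * S
    if np.all(np.abs(D - D[0]) <= 1e-12 * np.abs(D[0])):
        # common shape: the conditional problem tr(D^-1 R' M R) with
        # M = sum_j W_j / d_j has the exact eigendecomposition solution,
        # pairing the largest eigenvalues of M with the largest shape
        # elements
        M = np.einsum("k,kij->ij", 1.0 / d, W)
        _, evecs = _eigh_descending(M)
        R = np.empty((p, p))
        R[:, np.argsort(-D[0], kind="stable")] = _canonicalize_signs(evecs)
        return R, True
    omega = np.linalg.eigvalsh(W)[:, -1]
    A = 1.0 / (d[:, None] * D)  # (k, p) diagonals of A_j
    R = R_init
    converged = False
    eye = np.eye(p)
    for _ in range(max_iter):
        M = omega[:, None, None] * eye[None] - W  # (k, p, p), PSD
        G = np.einsum("kij,jl,kl->il", M, R, A)
        U, _, Vt = np.linalg.svd(G)
        R_new = U @ Vt
        delta = rotation_change(R, R_new)
        R = R_new
        if delta <= tol:
            converged = True
            break
    return R, converged


def _scatter_objective(S: np.ndarray, nj: np.ndarray, d, D, R) -> float:
    """Complete-data scatter objective sum_j n_j [log|Sigma_j| + tr(Sigma_j^-1 S_j)]."""
    p = S.shape[1]
    quad = np.einsum("kai,kab,kbi->ki", R, S, R)
    return float(np.sum(nj * (p * np.log(d) + np.sum(np.log(D), axis=1)
                              + np.sum(quad / D, axis=1) / d)))


def update_scatters(
    S: np.ndarray,
    nj: np.ndarray,
    spec: ConstraintSpec,
    max_iter_scatter: int = 20,
    max_iter_shape: int = 20,
    max_iter_rotation: int = 20,
    tol_scatter: float = 1e-6,
    tol_shape: float = 1e-6,
    tol_rotation: float = 1e-6,
    state=None,
):
    """Full constrained scatter update given weighted scatter matrices.

    Initializes volumes from ``|S_j|^(1/p)`` and rotations per the regime
    (per-component eigenvectors for "V", the identity for "I", eigenvectors
    of the pooled volume-standardized scatter for "E"), then cycles shape ->
    volume -> rotation conditional updates until the decomposition changes
    by less than ``tol_scatter``.  Returns ``(d, D, R, Sigma)`` with
    ``Sigma_j = d_j R_j diag(D_j) R_j'`` satisfying the constraints; under
    the free-rotation regime the shape elements are reordered non-increasing
    (with the matching rotation column permutation) before returning.

    ``state``, if given, is the previous iteration's decomposition
    ``(d, D, R)``; whenever the fresh alternation lands at a point with a
    worse complete-data objective than the previous (feasible) decomposition,
    the previous one is kept, which makes the enclosing EM/CEM iteration a
    monotone generalized-EM step.
    """
    k, p = S.shape[0], S.shape[1]
    n = nj.sum()
    sign, logdet = np.linalg.slogdet(S)
    scale = max(float(np.einsum("kii->", S)) / (k * p), _TINY)
    d = np.where(sign > 0, np.exp(logdet / p), 0.0)
    d = np.maximum(d, 1e-12 * scale)

    if spec.rotation == "V":
        _, evecs = _eigh_descending(S)
        R = np.stack([_canonicalize_signs(evecs[j]) for j in range(k)])
    elif spec.rotation == "I":
        R = np.broadcast_to(np.eye(p), (k, p, p)).copy()
    else:  # common rotation from the pooled standardized scatter
        pooled = np.einsum("k,kij->ij", nj / (n * d), S)
        _, evecs = _eigh_descending(pooled)
        R = np.broadcast_to(_canonicalize_signs(evecs), (k, p, p)).copy()

    D = None
    d_prev = R_prev = D_prev = None
    for _ in range(max_iter_scatter):
        D = update_shapes(S, nj, d, R, spec, max_iter=max_iter_shape, tol=tol_shape)
        d = update_volumes(S, nj, D, R, spec.c_det)
        if spec.rotation == "E" and p > 1:
            Rc, _ = update_rotation_common(
                S, nj, d, D, R[0], max_iter=max_iter_rotation, tol=tol_rotation
            )
            R = np.broadcast_to(Rc, (k, p, p)).copy()
        if d_prev is not None:
            delta = max(
                relative_change(d_prev, d),
                relative_change(D_prev, D),
                max(rotation_change(R_prev[j], R[j]) for j in range(k)),
            )
            if delta <= tol_scatter:
                break
        d_prev, D_prev, R_prev = d, D, R

    if state is not None:
        d0, D0, R0 = state
        if _scatter_objective(S, nj, d0, D0, R0) < _scatter_objective(S, nj, d, D, R):
            d, D, R = d0, D0, R0
    if spec.rotation == "V":
        # canonical non-increasing shape order, permuting eigenpairs jointly
        order = np.argsort(-D, axis=1, kind="stable")
        D = np.take_along_axis(D, order, axis=1)
        R = np.take_along_axis(R, order[:, None, :], axis=2)
    Sigma = compose_batch(d, D, R)
    return d, D, R, Sigma


# ---------------------------------------------------------------------------
# single-start ECM loop
# ---------------------------------------------------------------------------

def _target_from_log_weights(lw: np.ndarray, mode: str) -> float:
    if mode == "cem":
        return float(lw.max(axis=1).sum())
    return float(logsumexp(lw, axis=1).sum())


def _run_start(X, params, spec, mode, controls):
    """Iterate the ECM steps from one initialization until convergence.

    Returns a dict with the final parameters, target value, responsibilities,
    labels, iteration count, convergence flag and the per-iteration target
    history.  Raises :class:`DegenerateStartError` if a component collapses.
    """
    n = X.shape[0]
    history = []
    n_iter = 0
    converged = False
    state = None
    for n_iter in range(1, controls["max_iter"] + 1):
        tau, lw = e_step(X, params, mode)
        history.append(_target_from_log_weights(lw, mode))
        nj = tau.sum(axis=0)
        if np.any(nj < max(1e-10, n * 1e-12)):
            raise DegenerateStartError(
                f"component mass collapsed (n_j={nj.min():.3g}) at iteration {n_iter}"
            )
        pi, mu, nj, S = m_step_weights_means(X, tau)
        try:
            d, D, R, Sigma = update_scatters(
                S,
                nj,
                spec,
                max_iter_scatter=controls["max_iter_scatter"],
                max_iter_shape=controls["max_iter_shape"],
                max_iter_rotation=controls["max_iter_rotation"],
                tol_scatter=controls["tol_scatter"],
                tol_shape=controls["tol_shape"],
                tol_rotation=controls["tol_rotation"],
                state=state,
            )
        except DegenerateScatterError as exc:
            raise DegenerateStartError(str(exc)) from exc
        state = (d, D, R)
        new = MixtureParameters(
            weights=pi, means=mu, covariances=Sigma, volumes=d, shapes=D, rotations=R
        )
        delta = max(
            relative_change(params.weights, new.weights),
            relative_change(params.means, new.means),
            relative_change(params.covariances, new.covariances),
        )
        params = new
        if delta <= controls["tol"]:
            converged = True
            break
    tau, lw = e_step(X, params, mode)
    target = _target_from_log_weights(lw, mode)
    history.append(target)
    labels = np.argmax(lw, axis=1)
    return {
        "params": params,
        "target": target,
        "tau": tau,
        "labels": labels,
        "n_iter": n_iter,
        "converged": converged,
        "history": np.asarray(history),
    }


_ROT_CODE = {"I": 0, "E": 1, "V": 2}


def _run_start_fast(X, params, spec, mode, controls):
    """Dispatch one start to the numba-compiled mirror of ``_run_start``."""
    out = _ecm_fast.run_start(
        np.ascontiguousarray(X),
        params.weights,
        params.means,
        params.covariances,
        spec.c_det,
        spec.c_shw,
        spec.c_shb,
        _ROT_CODE[spec.rotation],
        mode == "cem",
        controls["max_iter"],
        controls["max_iter_scatter"],
        controls["max_iter_shape"],
        controls["max_iter_rotation"],
        controls["tol"],
        controls["tol_scatter"],
        controls["tol_shape"],
        controls["tol_rotation"],
    )
    (status, pi, mu, cov, d, D, R, tau, labels, n_iter, converged, target,
     history, hist_len) = out
    if status != 0:
        raise DegenerateStartError(f"start degenerated at iteration {n_iter}")
    return {
        "params": MixtureParameters(
            weights=pi, means=mu, covariances=cov, volumes=d, shapes=D, rotations=R
        ),
        "target": float(target),
        "tau": tau,
        "labels": labels,
        "n_iter": int(n_iter),
        "converged": bool(converged),
        "history": history[:hist_len].copy(),
    }


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ConstrainedGaussianMixture(ClusterMixin, BaseEstimator):
    """Gaussian mixture clustering under tunable covariance constraints.

    Parameters
    ----------
    n_components : int
        Number of mixture components ``k``.
    c_det, c_shw, c_shb : float
        Constraint constants (each >= 1, ``inf`` for unconstrained): maximal
        determinant ratio across components, maximal shape-element ratio
        within a component, and maximal per-coordinate shape-element ratio
        between components.  ``c_shb`` is capped at ``c_shw**((p-1)/p)``
        (with a warning) once the dimension is known.
    rotation : {"I", "E", "V"}
        Rotation regime: axis-aligned components, a common rotation, or free
        rotations.
    mode : {"em", "cem"}
        Maximize the mixture likelihood (EM, soft responsibilities) or the
        classification likelihood (CEM, hard assignments).
    n_init : int
        Number of random starts; the best target value is kept.
    max_iter, max_iter_scatter, max_iter_shape, max_iter_rotation : int
        Iteration caps for the outer ECM loop and the nested scatter, shape
        and rotation loops.
    tol, tol_scatter, tol_shape, tol_rotation : float
        Relative-change stopping tolerances for the same loops.
    random_state : int, Generator or None
        Seed for the independent per-start substreams.
    engine : {"auto", "numba", "numpy"}
        Inner-loop implementation: the numba-compiled fast path (used by
        "auto" when numba is importable) or the pure-numpy reference path.
        Both implement the identical algorithm.

    Attributes
    ----------
    weights_, means_, covariances_ : ndarray
        Fitted mixture parameters.
    volumes_, shapes_, rotations_ : ndarray
        The constrained decomposition of the fitted covariances.
    labels_ : ndarray of shape (n,)
        Hard assignments of the training data.
    log_likelihood_ : float
        The achieved target value (mixture or classification log-likelihood).
    constraint_report_ : ConstraintReport
        Achieved constraint ratios of the fitted parameters.
    """

    def __init__(
        self,
        n_components: int = 1,
        *,
        c_det: float = math.inf,
        c_shw: float = math.inf,
        c_shb: float = math.inf,
        rotation: str = "V",
        mode: str = "em",
        n_init: int = 50,
        max_iter: int = 100,
        max_iter_scatter: int = 20,
        max_iter_shape: int = 20,
        max_iter_rotation: int = 20,
        tol: float = 1e-6,
        tol_scatter: float = 1e-6,
        tol_shape: float = 1e-6,
        tol_rotation: float = 1e-6,
        random_state=None,
        engine: str = "auto",
    ):
        self.n_components = n_components
        self.c_det = c_det
        self.c_shw = c_shw
        self.c_shb = c_shb
        self.rotation = rotation
        self.mode = mode
        self.n_init = n_init
        self.max_iter = max_iter
        self.max_iter_scatter = max_iter_scatter
        self.max_iter_shape = max_iter_shape
        self.max_iter_rotation = max_iter_rotation
        self.tol = tol
        self.tol_scatter = tol_scatter
        self.tol_shape = tol_shape
        self.tol_rotation = tol_rotation
        self.random_state = random_state
        self.engine = engine

    # -- helpers ----------------------------------------------------------

    def _controls(self) -> dict:
        return {
            "max_iter": self.max_iter,
            "max_iter_scatter": self.max_iter_scatter,
            "max_iter_shape": self.max_iter_shape,
            "max_iter_rotation": self.max_iter_rotation,
            "tol": self.tol,
            "tol_scatter": self.tol_scatter,
            "tol_shape": self.tol_shape,
            "tol_rotation": self.tol_rotation,
        }

    def _spec(self, p: int) -> ConstraintSpec:
        return ConstraintSpec(
            c_det=self.c_det, c_shw=self.c_shw, c_shb=self.c_shb, rotation=self.rotation
        ).effective(p)

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the constrained mixture to ``X`` (n observations x p features)."""
        return self._fit(check_array(X, ensure_min_samples=2))

    def _fit(self, X: np.ndarray, extra_inits=()):
        n, p = X.shape
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        spec = self._spec(p)
        controls = self._controls()
        if isinstance(self.random_state, np.random.SeedSequence):
            ss = self.random_state
        else:
            ss = np.random.SeedSequence(self.random_state)
        rngs = [np.random.default_rng(c) for c in ss.spawn(self.n_init)]

        inits = [initialize_parameters(X, k, rng) for rng in rngs]
        inits.extend(extra_inits)

        if self.engine == "numba" or (self.engine == "auto" and _ecm_fast.HAVE_NUMBA):
            runner = _run_start_fast
        elif self.engine in ("auto", "numpy"):
            runner = _run_start
        else:
            raise ValueError(f"engine must be 'auto', 'numba' or 'numpy', got {self.engine!r}")

        best = None
        targets = []
        failures = 0
        for i, params0 in enumerate(inits):
            try:
                result = runner(X, params0, spec, self.mode, controls)
            except DegenerateStartError as exc:
                logger.debug("start %d degenerated: %s", i, exc)
                failures += 1
                continue
            targets.append(result["target"])
            logger.info("start %d: target %.6f", i, result["target"])
            if best is None or result["target"] > best["target"]:
                best = result
        if best is None:
            raise FitFailureError(
                f"all {len(inits)} starts degenerated (k={k}, spec={spec})"
            )

        params = best["params"]
        self.spec_ = spec
        self.n_features_in_ = p
        self.weights_ = params.weights
        self.means_ = params.means
        self.covariances_ = params.covariances
        self.volumes_ = params.volumes
        self.shapes_ = params.shapes
        self.rotations_ = params.rotations
        self.params_ = params
        self.labels_ = best["labels"]
        self.responsibilities_ = best["tau"]
        self.log_likelihood_ = best["target"]
        self.target_history_ = best["history"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.n_successful_inits_ = len(inits) - failures
        self.per_start_targets_ = targets
        # constraint satisfaction is guaranteed to the inner-loop tolerance
        self.constraint_report_ = check_constraints(params, spec, tol=1e-5)
        if not self.constraint_report_.satisfied:
            warnings.warn("fitted parameters exceed the constraint tolerance", UserWarning)
        return self

    # -- inference --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Hard component assignments (ties to the lowest index)."""
        check_is_fitted(self, "params_")
        lw = weighted_log_densities(check_array(X), self.params_)
        return np.argmax(lw, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior component probabilities."""
        check_is_fitted(self, "params_")
        lw = weighted_log_densities(check_array(X), self.params_)
        return np.exp(lw - logsumexp(lw, axis=1, keepdims=True))

    def score_samples(self, X) -> np.ndarray:
        """Per-observation mixture log-density."""
        check_is_fitted(self, "params_")
        return logsumexp(weighted_log_densities(check_array(X), self.params_), axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-observation mixture log-likelihood."""
        return float(np.mean(self.score_samples(X)))

    def mixture_log_likelihood(self, X) -> float:
        check_is_fitted(self, "params_")
        return mixture_loglik(X, self.params_)

    def classification_log_likelihood(self, X, labels) -> float:
        check_is_fitted(self, "params_")
        return classification_loglik(X, self.params_, labels)


def fit_mixture(X, k: int, spec: ConstraintSpec | None = None, **kwargs) -> ConstrainedGaussianMixture:
    """Functional wrapper around :class:`ConstrainedGaussianMixture`."""
    spec = spec or ConstraintSpec()
    est = ConstrainedGaussianMixture(
        n_components=k,
        c_det=spec.c_det,
        c_shw=spec.c_shw,
        c_shb=spec.c_shb,
        rotation=spec.rotation,
        **kwargs,
    )
    return est.fit(X)
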