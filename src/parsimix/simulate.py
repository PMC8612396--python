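"""Synthetic mixture designs, overlap-controlled generation and scoring.

Two fixed benchmark designs are provided: a three-component bivariate
configuration embedded in noise coordinates of variance 100, and a
six-component spherical configuration with one noise coordinate.  A random
generator produces k-component Gaussian mixtures whose covariances satisfy a
requested parsimonious constraint pattern and whose mean configuration is
rescaled so the average pairwise overlap (the summed directed
misclassification probabilities, averaged over component pairs) hits a
prefixed rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .constraints import ConstraintSpec, LimitModel, check_constraints, limit_model
from .exceptions import GenerationError
from .likelihood import weighted_log_densities
from .params import MixtureParameters
from .truncation import opt_trunc_batch

__all__ = [
    "make_design_A",
    "make_design_B",
    "sample_mixture",
    "pairwise_overlap",
    "generate_overlap_mixture",
    "adjusted_rand_index",
    "OverlapSummary",
]

#: Finite stand-ins used when a limit pattern's infinite constants must be
#: realized by concrete covariances: 100 for the determinant and shape-within
#: constants, 10 for shape-between.
FINITE_SUBSTITUTE_DET = 100.0
FINITE_SUBSTITUTE_SHW = 100.0
FINITE_SUBSTITUTE_SHB = 10.0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# fixed designs
# ---------------------------------------------------------------------------

def make_design_A(higher_p: bool = False, higher_n: bool = False, seed=None):
    """Three elliptical components plus high-variance noise coordinates.

    The informative plane holds bivariate normals with means (0,0), (2,6),
    (6,0) and diagonal covariances diag(2,2), diag(3,1), diag(1,2); a third
    (and, with ``higher_p``, a fourth) independent coordinate is N(0, 100)
    noise.  Component sizes are (50, 20, 20), doubled under ``higher_n``.
    Returns ``(X, labels, params)`` with the true mixture parameters.
    """
    rng = _rng(seed)
    p = 4 if higher_p else 3
    sizes = np.array([50, 20, 20]) * (2 if higher_n else 1)
    means2 = np.array([[0.0, 0.0], [2.0, 6.0], [6.0, 0.0]])
    vars2 = np.array([[2.0, 2.0], [3.0, 1.0], [1.0, 2.0]])
    means = np.zeros((3, p))
    means[:, :2] = means2
    covs = np.zeros((3, p, p))
    for j in range(3):
        diag = np.concatenate([vars2[j], np.full(p - 2, 100.0)])
        covs[j] = np.diag(diag)
    weights = sizes / sizes.sum()
    params = MixtureParameters(weights=weights, means=means, covariances=covs)
    X, labels = sample_mixture(params, sizes=sizes, seed=rng)
    return X, labels, params


def make_design_B(seed=None):
    """Six spherical bivariate components plus one noise coordinate.

    Means (-4.5, 3.6), (0.40, 3.6), (-4.4, -1), (9.2, -1), (0.4, -1),
    (9.2, 3.6), all sharing the same in-plane spherical scatter (unit
    variance), component sizes (23, 36, 93, 38, 123, 12), with an independent
    N(0, 100) third coordinate.
    """
    rng = _rng(seed)
    sizes = np.array([23, 36, 93, 38, 123, 12])
    means2 = np.array(
        [[-4.5, 3.6], [0.40, 3.6], [-4.4, -1.0], [9.2, -1.0], [0.4, -1.0], [9.2, 3.6]]
    )
    means = np.hstack([means2, np.zeros((6, 1))])
    covs = np.stack([np.diag([1.0, 1.0, 100.0])] * 6)
    weights = sizes / sizes.sum()
    params = MixtureParameters(weights=weights, means=means, covariances=covs)
    X, labels = sample_mixture(params, sizes=sizes, seed=rng)
    return X, labels, params


def sample_mixture(params: MixtureParameters, n: int | None = None, sizes=None, seed=None):
    """Draw observations from a Gaussian mixture.

    Either ``sizes`` (exact per-component counts) or ``n`` (multinomial
    counts by the mixture weights) must be given.  Returns ``(X, labels)``
    with 0-based labels.
    """
    rng = _rng(seed)
    k, p = params.means.shape
    if sizes is None:
        if n is None:
            raise ValueError("provide either n or sizes")
        sizes = rng.multinomial(n, params.weights)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.shape != (k,) or sizes.sum() < 1:
        raise ValueError("sizes must hold one nonnegative count per component")
    chunks = []
    labels = []
    L = np.linalg.cholesky(params.covariances)
    for j in range(k):
        z = rng.standard_normal((sizes[j], p))
        chunks.append(params.means[j] + z @ L[j].T)
        labels.append(np.full(sizes[j], j))
    return np.vstack(chunks), np.concatenate(labels)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapSummary:
    """Pairwise misclassification probabilities and their average.

    ``w[j, l]`` estimates ``P[pi_l phi_l(X) < pi_j phi_j(X)]`` for ``X``
    drawn from component ``l``; the average sums ``w[j, l] + w[l, j]`` over
    unordered pairs and divides by ``k (k - 1) / 2``.
    """

    w: np.ndarray
    average: float
    mc_draws: int


def _overlap_matrix(params: MixtureParameters, draws: np.ndarray) -> np.ndarray:
    """Directed misclassification matrix from per-component standard draws.

    ``draws`` has shape (k, m, p): common standard-normal variates that are
    affinely mapped through each component, enabling common-random-number
    reuse across candidate mean configurations.
    """
    k = params.n_components
    L = np.linalg.cholesky(params.covariances)
    w = np.zeros((k, k))
    for l in range(k):
        X = params.means[l] + draws[l] @ L[l].T
        lw = weighted_log_densities(X, params)  # (m, k)
        # w[j, l]: own weighted density falls below component j's
        w[:, l] = (lw[:, [l]] < lw).mean(axis=0)
    np.fill_diagonal(w, 0.0)
    return w


def pairwise_overlap(params: MixtureParameters, mc_draws: int = 100_000, seed=None) -> OverlapSummary:
    """Monte-Carlo estimate of the average pairwise overlap of a mixture.

    For each ordered pair (j, l), ``w[j, l]`` is the proportion of draws from
    component ``l`` whose weighted density under ``l`` falls below that under
    ``j``.
    """
    rng = _rng(seed)
    k, p = params.means.shape
    if k < 2:
        raise ValueError("overlap needs at least two components")
    draws = rng.standard_normal((k, int(mc_draws), p))
    w = _overlap_matrix(params, draws)
    average = float(w.sum() / (k * (k - 1) / 2))
    return OverlapSummary(w=w, average=average, mc_draws=int(mc_draws))


# ---------------------------------------------------------------------------
# overlap-controlled random mixtures
# ---------------------------------------------------------------------------

def _haar_orthogonal(p: int, rng: np.random.Generator) -> np.ndarray:
    Q, Rm = np.linalg.qr(rng.standard_normal((p, p)))
    return Q * np.sign(np.diag(Rm))


def _random_pattern_covariances(k: int, p: int, spec: ConstraintSpec, rng: np.random.Generator):
    """Random (volumes, shapes, rotations) satisfying a constraint pattern."""
    # volumes: determinant ratio <= c_det, log-uniform within the band
    if spec.c_det == 1:
        d = np.ones(k)
    else:
        d = np.exp(rng.uniform(0, math.log(spec.c_det) / p, size=k))
    # shapes: within-ratio then between-ratio imposed by truncation passes;
    # under the free-rotation regime shapes are kept in sorted order (the
    # between constraint applies to the ordered elements) -- the rotations
    # are arbitrary anyway
    if spec.c_shw == 1:
        D = np.ones((k, p))
    else:
        D = np.exp(rng.uniform(0, math.log(spec.c_shw), size=(k, p)))
        for _ in range(100):
            D = opt_trunc_batch(np.ones(p), D, spec.c_shw)
            D = D / np.exp(np.mean(np.log(D), axis=1))[:, None]
            if spec.rotation == "V":
                D = -np.sort(-D, axis=1)
            if spec.c_shb == 1:
                D = np.broadcast_to(np.exp(np.mean(np.log(D), axis=0)), (k, p)).copy()
            else:
                D = opt_trunc_batch(np.ones(k), D.T, spec.c_shb).T
            within = (D.max(axis=1) / D.min(axis=1) <= spec.c_shw * (1 + 1e-12)).all()
            between = (D.max(axis=0) / D.min(axis=0) <= spec.c_shb * (1 + 1e-12)).all()
            unit = np.allclose(np.mean(np.log(D), axis=1), 0, atol=1e-12)
            sorted_ok = spec.rotation != "V" or (np.diff(D, axis=1) <= 1e-12).all()
            if within and between and unit and sorted_ok:
                break
    # rotations per regime
    if spec.rotation == "I" or spec.c_shw == 1:
        R = np.broadcast_to(np.eye(p), (k, p, p)).copy()
    elif spec.rotation == "E":
        R = np.broadcast_to(_haar_orthogonal(p, rng), (k, p, p)).copy()
    else:
        R = np.stack([_haar_orthogonal(p, rng) for _ in range(k)])
    return d, D, R


def generate_overlap_mixture(
    k: int,
    p: int,
    model: str | LimitModel | ConstraintSpec = "VVV",
    target_overlap: float = 0.05,
    weights=None,
    seed=None,
    mc_draws: int = 50_000,
    tol: float = 0.005,
    max_tries: int = 10,
) -> MixtureParameters:
    """Random mixture with pattern-conforming covariances and fixed overlap.

    Covariances are drawn to satisfy the constraint pattern of ``model`` (a
    three-letter code, :class:`LimitModel` or explicit spec); infinite
    constants in a limit pattern are realized with the finite stand-ins 100
    (determinant, shape-within) and 10 (shape-between).  Means are drawn
    uniformly on a hypercube and the configuration is rescaled about its
    centroid by bisection until the Monte-Carlo average pairwise overlap is
    within ``tol`` of ``target_overlap``.
    """
    if not 0 < target_overlap < 1:
        raise ValueError("target_overlap must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = _rng(seed)
    if isinstance(model, str):
        model = limit_model(model)
    if isinstance(model, LimitModel):
        spec = model.spec(substitute=FINITE_SUBSTITUTE_DET, substitute_shb=FINITE_SUBSTITUTE_SHB)
        if math.isinf(model.limits[0]):
            spec = ConstraintSpec(
                FINITE_SUBSTITUTE_DET, spec.c_shw, spec.c_shb, spec.rotation
            )
    else:
        spec = model
    spec = spec.effective(p)
    weights = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)

    last_err = None
    for _ in range(max_tries):
        d, D, R = _random_pattern_covariances(k, p, spec, rng)
        mu0 = rng.uniform(0.0, 1.0, size=(k, p))
        center = mu0.mean(axis=0)
        draws = rng.standard_normal((k, mc_draws, p))

        def realized(scale: float) -> float:
            pars = MixtureParameters.from_decomposition(
                weights, center + scale * (mu0 - center), d, D, R
            )
            w = _overlap_matrix(pars, draws)
            return float(w.sum() / (k * (k - 1) / 2))

        # bracket the target: overlap decreases as the means spread out
        lo = hi = 1.0
        ov = realized(1.0)
        ok = True
        if ov > target_overlap:
            for _ in range(40):
                hi *= 2.0
                if realized(hi) <= target_overlap:
                    break
                lo = hi
            else:
                ok = False
        else:
            for _ in range(40):
                lo /= 2.0
                if realized(lo) >= target_overlap:
                    break
                hi = lo
            else:
                ok = False
        if not ok:
            last_err = f"could not bracket the target overlap (last scale {hi:.3g})"
            continue
        scale = hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            ov = realized(mid)
            if abs(ov - target_overlap) <= 0.5 * tol:
                scale = mid
                break
            if ov > target_overlap:
                lo = mid
            else:
                hi = mid
            scale = mid
        pars = MixtureParameters.from_decomposition(
            weights, center + scale * (mu0 - center), d, D, R
        )
        report = check_constraints(pars, spec, tol=1e-8)
        if not report.satisfied:
            last_err = f"generated covariances violate the pattern: {report}"
            continue
        if abs(realized(scale) - target_overlap) <= tol:
            return pars
        last_err = "bisection did not reach the overlap tolerance"
    raise GenerationError(f"overlap-controlled generation failed: {last_err}")


# ---------------------------------------------------------------------------
# partition scoring
# ---------------------------------------------------------------------------

def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))
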