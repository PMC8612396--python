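"""BIC-type model selection over constraint constants and component counts.

The criterion penalizes the maximized target log-likelihood ``L`` with a
complexity term that interpolates smoothly between the free-parameter counts
of the 14 classical parsimonious models:

    BIC[k, pars] = -2 L + v log n,
    v = kp + (k-1)
        + (k-1)(1 - c_det^(-1/p)) + 1
        + (p-1)(1 - 1/c_shw) [ (k-1)(1 - 1/c_shb) + 1 ]
        + k(rot) p(p-1)/2,

with ``k(rot)`` equal to 0, 1 or k for the identity, common and free rotation
regimes.  Lower BIC is better.  The search is two-phase: phase 1 fits every
``k`` at the 14 limit patterns (with infinity replaced by ``2**(C-1)``) and
fixes ``k``, the rotation regime, and any constants pinned at 1; phase 2
refines the remaining constants over powers of two.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import ConstraintSpec, enumerate_limit_models, shb_feasible_bound
from .exceptions import FitFailureError
from .mixture import ConstrainedGaussianMixture

logger = logging.getLogger(__name__)


def rotation_multiplicity(rotation: str, k: int) -> int:
    """Number of free rotation matrices: 0 (I), 1 (E) or k (V)."""
    return {"I": 0, "E": 1, "V": k}[rotation]


def penalty_terms(k: int, p: int, spec: ConstraintSpec) -> float:
    """Complexity penalty ``v`` of a constrained mixture configuration.

    At the limit configurations (constants 1 or infinity) this equals the
    classical free-parameter count of the corresponding three-letter model.
    """
    c_det, c_shw, c_shb = spec.c_det, spec.c_shw, spec.c_shb
    det_term = (k - 1) * (1.0 - (0.0 if math.isinf(c_det) else c_det ** (-1.0 / p))) + 1.0
    shw_frac = 1.0 if math.isinf(c_shw) else 1.0 - 1.0 / c_shw
    shb_frac = 1.0 if math.isinf(c_shb) else 1.0 - 1.0 / c_shb
    shape_term = (p - 1) * shw_frac * ((k - 1) * shb_frac + 1.0)
    rot_term = rotation_multiplicity(spec.rotation, k) * p * (p - 1) / 2.0
    return k * p + (k - 1) + det_term + shape_term + rot_term


def bic_score(loglik: float, k: int, p: int, n: int, spec: ConstraintSpec) -> float:
    """``-2 L + v log n``; lower is better."""
    return -2.0 * loglik + penalty_terms(k, p, spec) * math.log(n)


@dataclass
class SelectionResult:
    """Outcome of the two-phase BIC search."""

    table: pd.DataFrame
    k: int
    spec: ConstraintSpec
    bic: float
    phase1: dict
    estimator: ConstrainedGaussianMixture = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "spec": self.spec.to_dict(),
            "bic": self.bic,
            "loglik": self.estimator.log_likelihood_,
            "phase1": {
                "k": self.phase1["k"],
                "spec": self.phase1["spec"].to_dict(),
                "code": self.phase1["code"],
            },
        }


def _powers_of_two_up_to(bound: float, c_max: float) -> list[float]:
    limit = min(bound, c_max)
    vals = []
    v = 1.0
    while v <= limit * (1 + 1e-12):
        vals.append(v)
        v *= 2.0
    return vals


class ConstrainedMixtureSelector(ConstrainedGaussianMixture):
    """Two-phase BIC search over (k, c_det, c_shw, c_shb, rot).

    Parameters
    ----------
    max_components : int
        Upper bound K on the number of components.
    max_exponent : int
        Exponent bound C: infinite constants are replaced by ``2**(C-1)`` in
        phase 1 and the phase-2 refinement grid runs over powers of two up to
        the phase-1 choices.
    Other parameters are forwarded to :class:`ConstrainedGaussianMixture`.

    Attributes
    ----------
    table_ : DataFrame
        One row per evaluated configuration (phase, k, constants, rotation,
        loglik, penalty, BIC).
    k_, spec_, bic_ :
        The selected configuration.
    best_estimator_ : ConstrainedGaussianMixture
        The fit of the selected configuration.
    """

    def __init__(
        self,
        max_components: int = 5,
        max_exponent: int = 6,
        *,
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
        self.max_components = max_components
        self.max_exponent = max_exponent
        super().__init__(
            mode=mode,
            n_init=n_init,
            max_iter=max_iter,
            max_iter_scatter=max_iter_scatter,
            max_iter_shape=max_iter_shape,
            max_iter_rotation=max_iter_rotation,
            tol=tol,
            tol_scatter=tol_scatter,
            tol_shape=tol_shape,
            tol_rotation=tol_rotation,
            random_state=random_state,
            engine=engine,
        )

    def _make_estimator(self, k: int, spec: ConstraintSpec, seed) -> ConstrainedGaussianMixture:
        return ConstrainedGaussianMixture(
            n_components=k,
            c_det=spec.c_det,
            c_shw=spec.c_shw,
            c_shb=spec.c_shb,
            rotation=spec.rotation,
            mode=self.mode,
            n_init=self.n_init,
            max_iter=self.max_iter,
            max_iter_scatter=self.max_iter_scatter,
            max_iter_shape=self.max_iter_shape,
            max_iter_rotation=self.max_iter_rotation,
            tol=self.tol,
            tol_scatter=self.tol_scatter,
            tol_shape=self.tol_shape,
            tol_rotation=self.tol_rotation,
            random_state=seed,
            engine=self.engine,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        K, C = int(self.max_components), int(self.max_exponent)
        if K < 1 or C < 1:
            raise ValueError("max_components and max_exponent must be >= 1")
        c_max = 2.0 ** (C - 1)
        ss = np.random.SeedSequence(self.random_state)

        rows = []
        fits: dict[tuple, ConstrainedGaussianMixture] = {}

        def _evaluate(phase, k, spec, code, seed, extra_inits=()):
            key = (k, spec.c_det, spec.c_shw, spec.c_shb, spec.rotation)
            est = fits.get(key)
            if est is None:
                est = self._make_estimator(k, spec, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    try:
                        est._fit(X, extra_inits=extra_inits)
                    except FitFailureError as exc:
                        warnings.warn(
                            f"configuration k={k}, {code or spec} failed: {exc}",
                            UserWarning,
                        )
                        return None
                fits[key] = est
            v = penalty_terms(k, p, spec)
            bic = bic_score(est.log_likelihood_, k, p, n, spec)
            rows.append(
                {
                    "phase": phase,
                    "k": k,
                    "model": code,
                    "c_det": spec.c_det,
                    "c_shw": spec.c_shw,
                    "c_shb": spec.c_shb,
                    "rotation": spec.rotation,
                    "loglik": est.log_likelihood_,
                    "penalty": v,
                    "bic": bic,
                }
            )
            return est, v, bic, spec

        # ---- phase 1: K x 14 slightly constrained limit patterns ----------
        limit_models = enumerate_limit_models()
        phase1_best = None
        for k in range(1, K + 1):
            for model in limit_models:
                spec = model.spec(substitute=c_max)
                cap = shb_feasible_bound(spec.c_shw, p)
                if spec.c_shb > cap:
                    spec = ConstraintSpec(spec.c_det, spec.c_shw, cap, spec.rotation)
                out = _evaluate(1, k, spec, model.code, ss.spawn(1)[0])
                if out is None:
                    continue
                est, v, bic, spec = out
                cand = (bic, v, k)
                if phase1_best is None or cand < (
                    phase1_best["bic"],
                    phase1_best["v"],
                    phase1_best["k"],
                ):
                    phase1_best = {
                        "bic": bic,
                        "v": v,
                        "k": k,
                        "spec": spec,
                        "code": model.code,
                        "est": est,
                    }
        if phase1_best is None:
            raise FitFailureError("every phase-1 configuration failed")
        k_star = phase1_best["k"]
        spec_star = phase1_best["spec"]
        logger.info(
            "phase 1: k=%d %s (BIC %.3f)", k_star, phase1_best["code"], phase1_best["bic"]
        )

        # ---- phase 2: refine the constants over powers of two -------------
        det_axis = _powers_of_two_up_to(spec_star.c_det, c_max)
        shw_axis = _powers_of_two_up_to(spec_star.c_shw, c_max)
        shb_bound = min(spec_star.c_shb, shb_feasible_bound(spec_star.c_shw, p))
        shb_axis = _powers_of_two_up_to(shb_bound, c_max)
        warm = (phase1_best["est"].params_,)
        best = None
        for c_det in det_axis:
            for c_shw in shw_axis:
                for c_shb in shb_axis:
                    if c_shb > shb_feasible_bound(c_shw, p) * (1 + 1e-12):
                        continue  # infeasible triple: the bound can never bind
                    spec = ConstraintSpec(c_det, c_shw, c_shb, spec_star.rotation)
                    out = _evaluate(2, k_star, spec, None, ss.spawn(1)[0], extra_inits=warm)
                    if out is None:
                        continue
                    est, v, bic, spec = out
                    cand = (bic, v)
                    if best is None or cand < (best["bic"], best["v"]):
                        best = {"bic": bic, "v": v, "spec": spec, "est": est}
        if best is None:
            raise FitFailureError("every phase-2 configuration failed")

        table = pd.DataFrame(rows)
        self.table_ = table
        self.k_ = k_star
        self.spec_ = best["spec"]
        self.bic_ = best["bic"]
        self.phase1_ = {
            "k": k_star,
            "spec": spec_star,
            "code": phase1_best["code"],
            "bic": phase1_best["bic"],
        }
        self.best_estimator_ = best["est"]
        self.n_features_in_ = p
        self.labels_ = best["est"].labels_
        self.result_ = SelectionResult(
            table=table,
            k=k_star,
            spec=best["spec"],
            bic=best["bic"],
            phase1=self.phase1_,
            estimator=best["est"],
        )
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)

    def score(self, X, y=None):
        return self.best_estimator_.score(X)


def select_model(X, K: int = 5, C: int = 6, **kwargs) -> SelectionResult:
    """Run the two-phase BIC search; functional wrapper over the selector."""
    sel = ConstrainedMixtureSelector(max_components=K, max_exponent=C, **kwargs)
    sel.fit(X)
    return sel.result_
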