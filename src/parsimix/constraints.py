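"""Constraint specifications for parsimonious Gaussian mixtures.

A fitted mixture's component covariances ``Sigma_j`` are decomposed as
``Sigma_j = d_j R_j D_j R_j'`` with volume ``d_j = |Sigma_j|^(1/p) > 0``,
unit-determinant diagonal shape ``D_j`` and orthogonal rotation ``R_j``.
Three tunable constants bound, across and within components,

* ``c_det``  -- the maximal ratio of covariance determinants,
* ``c_shw``  -- the maximal ratio of shape elements within one component
  ("shape-within"; ``c_shw = 1`` forces spherical components),
* ``c_shb``  -- the maximal ratio, per coordinate, of shape elements across
  components ("shape-between"; ``c_shb = 1`` forces a common shape),

and a rotation regime ``rot`` in ``{"I", "E", "V"}`` fixes the rotations to
the identity, a common orthogonal matrix, or leaves them free.  Sending each
constant to 1 or infinity recovers the 14 classical three-letter parsimonious
models (EII ... VVV) as limit cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

ROTATIONS = ("I", "E", "V")

#: Numeric surrogate for an effectively unconstrained constant, accepted on
#: input wherever "inf" is.
UNCONSTRAINED_SURROGATE = 1e10


def shb_feasible_bound(c_shw: float, p: int) -> float:
    """Largest shape-between constant that can ever bind given ``c_shw``.

    If every component satisfies the shape-within constraint at ``c_shw``,
    then any cross-component ratio of shape elements at a fixed coordinate is
    automatically bounded by ``c_shw ** ((p - 1) / p)``; a larger ``c_shb``
    is never active.  For ``p = 2`` this is ``sqrt(c_shw)``, and ``c_shw = 1``
    forces ``c_shb = 1``.
    """
    if c_shw < 1:
        raise ValueError(f"c_shw must be >= 1, got {c_shw}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if math.isinf(c_shw):
        return math.inf
    return float(c_shw) ** ((p - 1) / p)


def _validate_constant(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value) or value < 1:
        raise ValueError(f"{name} must be >= 1 or inf, got {value}")
    return value


@dataclass(frozen=True)
class ConstraintSpec:
    """The tuple ``(c_det, c_shw, c_shb, rotation)`` defining the feasible set.

    Constants equal to ``inf`` are represented exactly and short-circuit the
    truncation machinery.  ``c_shw = 1`` implies an effective ``c_shb = 1``.
    """

    c_det: float = math.inf
    c_shw: float = math.inf
    c_shb: float = math.inf
    rotation: str = "V"

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_det", _validate_constant("c_det", self.c_det))
        object.__setattr__(self, "c_shw", _validate_constant("c_shw", self.c_shw))
        object.__setattr__(self, "c_shb", _validate_constant("c_shb", self.c_shb))
        if self.rotation not in ROTATIONS:
            raise ValueError(
                f"rotation must be one of {ROTATIONS}, got {self.rotation!r}"
            )

    def effective(self, p: int) -> "ConstraintSpec":
        """Return the spec with ``c_shb`` capped at its feasible bound in R^p.

        Sphericity (``c_shw = 1``) forces ``c_shb = 1``; otherwise values of
        ``c_shb`` above ``c_shw ** ((p-1)/p)`` can never bind and are clamped
        with a warning.
        """
        cap = shb_feasible_bound(self.c_shw, p)
        if self.c_shb <= cap:
            return self
        warnings.warn(
            f"c_shb={self.c_shb} exceeds the feasible bound "
            f"c_shw**((p-1)/p)={cap:.6g} for p={p}; using c_shb={cap:.6g}",
            UserWarning,
            stacklevel=2,
        )
        return replace(self, c_shb=cap)

    @property
    def is_unconstrained(self) -> bool:
        return (
            math.isinf(self.c_det)
            and math.isinf(self.c_shw)
            and math.isinf(self.c_shb)
            and self.rotation == "V"
        )

    def to_dict(self) -> dict:
        def _ser(x: float):
            return "inf" if math.isinf(x) else x

        return {
            "c_det": _ser(self.c_det),
            "c_shw": _ser(self.c_shw),
            "c_shb": _ser(self.c_shb),
            "rotation": self.rotation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintSpec":
        def _de(x):
            return math.inf if x in ("inf", "Infinity", None) else float(x)

        return cls(
            c_det=_de(d["c_det"]),
            c_shw=_de(d["c_shw"]),
            c_shb=_de(d["c_shb"]),
            rotation=d["rotation"],
        )


@dataclass(frozen=True)
class LimitModel:
    """One of the 14 classical parsimonious models seen as a limit case.

    ``limits`` holds the constraint pattern ``(c_det, c_shw, c_shb, rotation)``
    with each constant either ``1`` or ``inf``.
    """

    code: str
    limits: tuple

    def spec(self, substitute: float = math.inf, substitute_shb: float | None = None) -> ConstraintSpec:
        """Constraint spec for this pattern, optionally replacing ``inf``.

        ``substitute`` replaces infinite ``c_det``/``c_shw`` values and
        ``substitute_shb`` (defaulting to ``substitute``) infinite ``c_shb``.
        """
        if substitute_shb is None:
            substitute_shb = substitute
        c_det, c_shw, c_shb, rot = self.limits
        return ConstraintSpec(
            c_det=substitute if math.isinf(c_det) else c_det,
            c_shw=substitute if math.isinf(c_shw) else c_shw,
            c_shb=substitute_shb if math.isinf(c_shb) else c_shb,
            rotation=rot,
        )


def raw_limit_combinations() -> list[tuple]:
    """All 2^3 x 3 = 24 raw limit patterns before feasibility filtering."""
    inf = math.inf
    return [
        (c_det, c_shw, c_shb, rot)
        for c_det in (1.0, inf)
        for c_shw in (1.0, inf)
        for c_shb in (1.0, inf)
        for rot in ROTATIONS
    ]


def _pattern_code(c_det: float, c_shw: float, c_shb: float, rot: str) -> str:
    vol = "E" if c_det == 1 else "V"
    if c_shw == 1:
        return vol + "II"
    shape = "E" if c_shb == 1 else "V"
    return vol + shape + rot


def enumerate_limit_models() -> list[LimitModel]:
    """Enumerate the 14 feasible limit models.

    Starting from the 24 raw combinations of the three constants in
    ``{1, inf}`` and the three rotation regimes, patterns with ``c_shw = 1``
    and ``c_shb = inf`` are infeasible (sphericity forces a common shape) and
    spherical patterns are rotation-invariant, so the 24 collapse to the 14
    classical parsimonious models.
    """
    seen: dict[str, LimitModel] = {}
    for c_det, c_shw, c_shb, rot in raw_limit_combinations():
        if c_shw == 1 and math.isinf(c_shb):
            continue  # infeasible: sphericity forces c_shb = 1
        code = _pattern_code(c_det, c_shw, c_shb, rot)
        canon_rot = "I" if c_shw == 1 else rot
        if code not in seen:
            seen[code] = LimitModel(code=code, limits=(c_det, c_shw, c_shb, canon_rot))
    # present in the conventional order: E* models before V* models
    order = [
        "EII", "EEI", "EEE", "EEV", "EVI", "EVE", "EVV",
        "VII", "VEI", "VEE", "VEV", "VVI", "VVE", "VVV",
    ]
    assert set(seen) == set(order), sorted(seen)
    return [seen[c] for c in order]


def limit_model(code: str) -> LimitModel:
    """Look up a limit model by its three-letter code."""
    for m in enumerate_limit_models():
        if m.code == code.upper():
            return m
    raise KeyError(f"unknown parsimonious model code {code!r}")


@dataclass(frozen=True)
class ConstraintReport:
    """Achieved constraint ratios of a parameter set against a spec.

    ``deter_ratio`` is the max/min ratio of covariance determinants,
    ``shw_ratios`` the per-component max/min shape-element ratios and
    ``shb_ratios`` the per-coordinate cross-component shape ratios.
    """

    deter_ratio: float
    shw_ratios: np.ndarray
    shb_ratios: np.ndarray
    satisfied: bool
    tolerance: float
    spec: ConstraintSpec = field(repr=False)


def check_constraints(params, spec: ConstraintSpec, tol: float = 1e-8) -> ConstraintReport:
    """Report the achieved constraint ratios of ``params`` against ``spec``.

    Ratios are computed from the volume/shape decomposition of the component
    covariances; the report is always returned, with ``satisfied`` true when
    every ratio is within its constant up to relative tolerance ``tol``.
    The shape-between ratios are evaluated coordinate-wise on the stored
    shapes (which, under the free-rotation regime, are in non-increasing
    order by convention).
    """
    params = params.with_decomposition(spec.rotation)
    vols = np.asarray(params.volumes, dtype=float)
    shapes = np.asarray(params.shapes, dtype=float)  # (k, p)
    p = shapes.shape[1]
    dets = vols**p
    deter_ratio = float(dets.max() / dets.min())
    shw_ratios = shapes.max(axis=1) / shapes.min(axis=1)  # (k,)
    shb_ratios = shapes.max(axis=0) / shapes.min(axis=0)  # (p,)
    satisfied = bool(
        deter_ratio <= spec.c_det * (1 + tol)
        and np.all(shw_ratios <= spec.c_shw * (1 + tol))
        and np.all(shb_ratios <= spec.c_shb * (1 + tol))
    )
    return ConstraintReport(
        deter_ratio=deter_ratio,
        shw_ratios=shw_ratios,
        shb_ratios=shb_ratios,
        satisfied=satisfied,
        tolerance=tol,
        spec=spec,
    )
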