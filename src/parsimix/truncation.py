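"""Weighted optimal truncation of nonnegative values to a ratio constraint.

Given nonnegative values ``v_1..v_m`` with nonnegative weights ``n_1..n_m``
and a constant ``c >= 1``, the operator clamps every value into an interval
``[t, c*t]``, choosing the threshold ``t`` to minimize the likelihood-derived
objective

    f(t) = sum_j n_j [ log m_t(v_j) + v_j / m_t(v_j) ],
    m_t(v) = min(max(v, t), c*t).

This is the elementary step used to impose the determinant-ratio and both
shape-ratio constraints inside the M-step of the constrained ECM algorithm.
The minimizer is found exactly: ``f`` is piecewise smooth with breakpoints
where the clamping pattern changes (at the values ``v_j`` and ``v_j / c``),
and on each piece the stationary threshold has the closed form

    t = ( sum_{j in L} n_j v_j + c^{-1} sum_{j in U} n_j v_j )
        / sum_{j in L u U} n_j,

with ``L = {j : v_j < t}`` (clamped up) and ``U = {j : v_j > c t}`` (clamped
down); ``f`` is evaluated at every breakpoint and every clipped stationary
candidate and the best is taken.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import DegenerateScatterError

__all__ = ["opt_trunc", "opt_trunc_batch", "trunc_objective"]


def trunc_objective(weights, values, t: float, c: float) -> float:
    """Evaluate the truncation objective ``f(t)`` at a threshold ``t > 0``.

    Entries with zero weight do not contribute.  ``c = inf`` clamps from
    below only.
    """
    if t <= 0:
        raise ValueError(f"threshold t must be positive, got {t}")
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    w = np.broadcast_to(w, v.shape)
    upper = np.inf if math.isinf(c) else c * t
    m = np.clip(v, t, upper)
    return float(np.sum(w * (np.log(m) + v / m)))


def opt_trunc(weights, values, c: float) -> np.ndarray:
    """Optimally truncate ``values`` so that ``max/min <= c``.

    Returns the clamped values ``m_t*(v_j)`` for the optimal threshold.  If
    the input already satisfies the ratio constraint (or ``c`` is infinite)
    it is returned unchanged.  Entries with zero weight are clamped by the
    final threshold but do not influence it.  Raises
    :class:`DegenerateScatterError` when every positively weighted value is
    zero (a collapsed component the caller must handle).
    """
    values = np.asarray(values, dtype=float)
    return opt_trunc_batch(weights, values[None, :], c)[0]


def opt_trunc_batch(weights, values: np.ndarray, c: float) -> np.ndarray:
    """Vectorized :func:`opt_trunc` over a batch of independent tasks.

    ``values`` has shape (B, m); ``weights`` is (m,) or (B, m) and is
    broadcast.  Each row is solved independently with the shared constant
    ``c``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be 2-D (batch, m)")
    B, m = v.shape
    w = np.broadcast_to(np.asarray(weights, dtype=float), v.shape)
    if np.any(w < 0) or np.any(v < 0):
        raise ValueError("weights and values must be nonnegative")
    if c < 1:
        raise ValueError(f"c must be >= 1, got {c}")
    pos = w > 0
    if not pos.any(axis=1).all():
        raise ValueError("each task needs at least one positive weight")
    degenerate = ~np.any(pos & (v > 0), axis=1)
    if degenerate.any():
        raise DegenerateScatterError(
            f"all positively weighted values are zero in tasks {np.flatnonzero(degenerate)}"
        )
    if math.isinf(c):
        return v.copy()

    vmin = v.min(axis=1)
    vmax = v.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = np.where(vmin > 0, vmax / vmin, np.where(vmax == 0, 1.0, np.inf)) <= c
    if ok.all():
        return v.copy()

    # breakpoints where the clamping pattern changes
    bp = np.sort(np.concatenate([v, v / c], axis=1), axis=1)  # (B, 2m)
    lo = np.concatenate([np.zeros((B, 1)), bp], axis=1)  # (B, 2m+1)
    hi = np.concatenate([bp, np.full((B, 1), np.inf)], axis=1)
    mid = np.where(np.isinf(hi), bp[:, -1:] * 1.5 + 1.0, 0.5 * (lo + hi))

    # stationary threshold on each interval, from the clamping pattern there
    L = v[:, None, :] < mid[:, :, None]  # (B, I, m)
    U = v[:, None, :] > c * mid[:, :, None]
    wv = w * v
    num = np.einsum("bim,bm->bi", L, wv) + np.einsum("bim,bm->bi", U, wv) / c
    den = np.einsum("bim,bm->bi", L | U, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(den > 0, num / den, np.nan)
    t_stat = np.clip(t_stat, lo, hi)

    cand = np.concatenate([bp, t_stat], axis=1)  # (B, 4m+1)
    cand = np.where(cand > 0, cand, np.nan)

    mclip = np.clip(v[:, None, :], cand[:, :, None], c * cand[:, :, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.einsum("bm,bcm->bc", w, np.log(mclip) + v[:, None, :] / mclip)
    f = np.where(np.isnan(f), np.inf, f)
    t_best = cand[np.arange(B), np.argmin(f, axis=1)]

    out = np.clip(v, t_best[:, None], c * t_best[:, None])
    out[ok] = v[ok]
    return out
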