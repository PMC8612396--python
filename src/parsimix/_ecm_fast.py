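"""Numba-compiled fast path for the single-start nested ECM loop.

This module mirrors, step for step, the reference numpy implementation in
:mod:`parsimix.mixture` (E-step, weight/mean updates, the truncation-based
shape/volume/rotation scatter update with the monotone fallback, and the
relative-change stopping rules).  It exists purely for speed: the estimator
dispatches here when numba is importable and falls back to the reference
path otherwise, and the two paths are held together by an equivalence test.

Status codes returned by :func:`run_start`: 0 = OK, 1 = degenerate start
(collapsed component mass or scatter).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_LOG_2PI = np.log(2.0 * np.pi)

# rotation regime codes
ROT_I, ROT_E, ROT_V = 0, 1, 2


@njit(cache=True)
def _trunc_f(w, v, t, c):
    """Truncation objective f(t) = sum w_j (log m + v/m), m = clip(v; t, ct)."""
    up = c * t
    f = 0.0
    for j in range(v.size):
        if w[j] <= 0.0:
            continue
        m = v[j]
        if m < t:
            m = t
        elif m > up:
            m = up
        f += w[j] * (np.log(m) + v[j] / m)
    return f


@njit(cache=True)
def _opt_trunc_row(w, v, c, out):
    """Exact optimal truncation of one task; returns 0 (ok) or 1 (degenerate)."""
    m = v.size
    anypos = False
    vmin = np.inf
    vmax = 0.0
    for j in range(m):
        if v[j] < vmin:
            vmin = v[j]
        if v[j] > vmax:
            vmax = v[j]
        if w[j] > 0.0 and v[j] > 0.0:
            anypos = True
    if not anypos:
        return 1
    if not np.isfinite(c) or vmax == 0.0 or (vmin > 0.0 and vmax / vmin <= c):
        for j in range(m):
            out[j] = v[j]
        return 0
    bp = np.empty(2 * m)
    for j in range(m):
        bp[j] = v[j]
        bp[m + j] = v[j] / c
    bp.sort()
    best_f = np.inf
    best_t = -1.0
    for i in range(2 * m + 1):
        lo = 0.0 if i == 0 else bp[i - 1]
        if i < 2 * m:
            hi = bp[i]
            tm = 0.5 * (lo + hi)
        else:
            hi = np.inf
            tm = bp[2 * m - 1] * 1.5 + 1.0
        # stationary threshold from the clamping pattern on this interval
        num = 0.0
        den = 0.0
        for j in range(m):
            if v[j] < tm:
                num += w[j] * v[j]
                den += w[j]
            elif v[j] > c * tm:
                num += w[j] * v[j] / c
                den += w[j]
        if den > 0.0:
            ts = num / den
            if ts < lo:
                ts = lo
            elif ts > hi:
                ts = hi
            if ts > 0.0:
                f = _trunc_f(w, v, ts, c)
                if f < best_f:
                    best_f = f
                    best_t = ts
        if i < 2 * m and bp[i] > 0.0:
            f = _trunc_f(w, v, bp[i], c)
            if f < best_f:
                best_f = f
                best_t = bp[i]
    up = c * best_t
    for j in range(m):
        o = v[j]
        if o < best_t:
            o = best_t
        elif o > up:
            o = up
        out[j] = o
    return 0


@njit(cache=True)
def _log_densities(X, pi, mu, cov, lw):
    """Weighted log-densities log(pi_j phi_j(x_i)); returns 0 or 1 (singular)."""
    n, p = X.shape
    k = pi.size
    y = np.empty(p)
    for j in range(k):
        L = np.linalg.cholesky(cov[j])
        logdet = 0.0
        for a in range(p):
            if L[a, a] <= 0.0 or not np.isfinite(L[a, a]):
                return 1
            logdet += 2.0 * np.log(L[a, a])
        const = np.log(pi[j]) - 0.5 * (p * _LOG_2PI + logdet)
        for i in range(n):
            # forward substitution L y = x - mu
            for a in range(p):
                s = X[i, a] - mu[j, a]
                for b in range(a):
                    s -= L[a, b] * y[b]
                y[a] = s / L[a, a]
            maha = 0.0
            for a in range(p):
                maha += y[a] * y[a]
            lw[i, j] = const - 0.5 * maha
    return 0


@njit(cache=True)
def _e_step(lw, hard, tau):
    """Responsibilities from weighted log-densities; returns the target value."""
    n, k = lw.shape
    target = 0.0
    for i in range(n):
        mx = lw[i, 0]
        arg = 0
        for j in range(1, k):
            if lw[i, j] > mx:
                mx = lw[i, j]
                arg = j
        if hard:
            for j in range(k):
                tau[i, j] = 0.0
            tau[i, arg] = 1.0
            target += mx
        else:
            s = 0.0
            for j in range(k):
                e = np.exp(lw[i, j] - mx)
                tau[i, j] = e
                s += e
            for j in range(k):
                tau[i, j] /= s
            target += mx + np.log(s)
    return target


@njit(cache=True)
def _m_step(X, tau, pi, mu, nj, S):
    n, p = X.shape
    k = pi.size
    for j in range(k):
        nj[j] = 0.0
        for i in range(n):
            nj[j] += tau[i, j]
        pi[j] = nj[j] / n
        for a in range(p):
            s = 0.0
            for i in range(n):
                s += tau[i, j] * X[i, a]
            mu[j, a] = s / nj[j]
        for a in range(p):
            for b in range(a + 1):
                s = 0.0
                for i in range(n):
                    s += tau[i, j] * (X[i, a] - mu[j, a]) * (X[i, b] - mu[j, b])
                S[j, a, b] = s / nj[j]
                S[j, b, a] = S[j, a, b]


@njit(cache=True)
def _canon_signs(R):
    p = R.shape[0]
    for c in range(p):
        for r in range(p):
            if abs(R[r, c]) > 1e-12:
                if R[r, c] < 0.0:
                    for rr in range(p):
                        R[rr, c] = -R[rr, c]
                break


@njit(cache=True)
def _quad_diag(R, S, out):
    """out[i] = (R' S R)_{ii}."""
    p = R.shape[0]
    for i in range(p):
        acc = 0.0
        for a in range(p):
            t = 0.0
            for b in range(p):
                t += S[a, b] * R[b, i]
            acc += R[a, i] * t
        out[i] = acc


@njit(cache=True)
def _rel_change(prev, curr):
    """max_j ||curr_j - prev_j|| / ||prev_j|| over the leading axis."""
    k = prev.shape[0]
    pv = prev.reshape(k, -1)
    cv = curr.reshape(k, -1)
    worst = 0.0
    for j in range(k):
        base = 0.0
        diff = 0.0
        for a in range(pv.shape[1]):
            base += pv[j, a] * pv[j, a]
            d = cv[j, a] - pv[j, a]
            diff += d * d
        if base > 0.0:
            r = np.sqrt(diff / base)
        elif diff > 0.0:
            r = np.inf
        else:
            r = 0.0
        if r > worst:
            worst = r
    return worst


@njit(cache=True)
def _rot_change(R_prev, R_curr):
    p = R_prev.shape[0]
    A = (R_curr.T @ R_prev).T
    B = R_curr @ R_prev.T
    tr = 0.0
    M = A @ B
    for i in range(p):
        tr += M[i, i]
    return abs(p - tr) / p


@njit(cache=True)
def _update_shapes(S, nj, d, R, c_shw, c_shb, rot, max_iter, tol, D_out):
    """Constrained shape update; returns 0 ok / 1 degenerate."""
    k, p = D_out.shape
    if c_shw == 1.0:
        for j in range(k):
            for a in range(p):
                D_out[j, a] = 1.0
        return 0
    base = np.empty((k, p))
    tmp = np.empty(p)
    for j in range(k):
        if rot == ROT_I:
            for a in range(p):
                base[j, a] = S[j, a, a] / d[j]
        else:
            _quad_diag(R[j], S[j], tmp)
            for a in range(p):
                base[j, a] = tmp[a] / d[j]
    if not np.isfinite(c_shw) and not np.isfinite(c_shb):
        # unconstrained shapes: floor vanished elements, normalize
        for j in range(k):
            mx = 0.0
            for a in range(p):
                if base[j, a] > mx:
                    mx = base[j, a]
            if mx <= 0.0:
                return 1
            g = 0.0
            for a in range(p):
                if base[j, a] < 1e-12 * mx:
                    base[j, a] = 1e-12 * mx
                g += np.log(base[j, a])
            g = np.exp(g / p)
            for a in range(p):
                D_out[j, a] = base[j, a] / g
        return 0
    Dp = base
    E = np.empty((k, p))
    col = np.empty(k)
    colo = np.empty(k)
    order = np.empty((k, p), dtype=np.int64)
    ones = np.ones(p)
    for _ in range(max_iter):
        # within constraint, per component, unit weights
        for j in range(k):
            st = _opt_trunc_row(ones, Dp[j], c_shw, E[j])
            if st != 0:
                return 1
        if rot == ROT_V:
            for j in range(k):
                order[j] = np.argsort(-E[j])
                for a in range(p):
                    tmp[a] = E[j, order[j, a]]
                for a in range(p):
                    E[j, a] = tmp[a]
        # between constraint, per coordinate, weights n_j
        for a in range(p):
            for j in range(k):
                col[j] = E[j, a]
            st = _opt_trunc_row(nj, col, c_shb, colo)
            if st != 0:
                return 1
            for j in range(k):
                E[j, a] = colo[j]
        if rot == ROT_V:
            for j in range(k):
                for a in range(p):
                    tmp[order[j, a]] = E[j, a]
                for a in range(p):
                    E[j, a] = tmp[a]
        # determinant normalization after the truncations: the between step
        # then acts on the raw conditional maximizers
        for j in range(k):
            g = 0.0
            for a in range(p):
                g += np.log(E[j, a])
            g = np.exp(g / p)
            for a in range(p):
                E[j, a] /= g
        delta = _rel_change(Dp, E)
        for j in range(k):
            for a in range(p):
                Dp[j, a] = E[j, a]
        if delta <= tol:
            break
    for j in range(k):
        for a in range(p):
            D_out[j, a] = Dp[j, a]
    return 0


@njit(cache=True)
def _update_volumes(S, nj, D, R, c_det, d_out):
    """Constrained volume update; returns 0 ok / 1 degenerate."""
    k, p = D.shape
    nu = np.empty(k)
    tmp = np.empty(p)
    for j in range(k):
        _quad_diag(R[j], S[j], tmp)
        s = 0.0
        for a in range(p):
            s += tmp[a] / D[j, a]
        nu[j] = s / p
    if not np.isfinite(c_det):
        mx = 0.0
        for j in range(k):
            if nu[j] > mx:
                mx = nu[j]
        if mx <= 0.0:
            return 1
        for j in range(k):
            d_out[j] = nu[j] if nu[j] > 1e-12 * mx else 1e-12 * mx
        return 0
    return _opt_trunc_row(nj, nu, c_det ** (1.0 / p), d_out)


@njit(cache=True)
def _update_rotation_common(S, nj, d, D, R0, max_iter, tol):
    """Majorization update of the common rotation; returns the new R."""
    k, p = D.shape
    n = 0.0
    for j in range(k):
        n += nj[j]
    same = True
    for j in range(1, k):
        for a in range(p):
            if abs(D[j, a] - D[0, a]) > 1e-12 * abs(D[0, a]):
                same = False
                break
        if not same:
            break
    if same:
        # common shape: exact conditional solution by eigendecomposition of
        # M = sum_j W_j / d_j, pairing largest eigenvalues with largest
        # shape elements
        M = np.zeros((p, p))
        for j in range(k):
            w = nj[j] / (n * d[j])
            for a in range(p):
                for b in range(p):
                    M[a, b] += w * S[j, a, b]
        evm, Vm = np.linalg.eigh(M)
        V = np.empty((p, p))
        for a in range(p):
            for b in range(p):
                V[a, b] = Vm[a, p - 1 - b]
        _canon_signs(V)
        order = np.argsort(-D[0])
        R = np.empty((p, p))
        for i in range(p):
            for a in range(p):
                R[a, order[i]] = V[a, i]
        return R
    R = R0.copy()
    G = np.empty((p, p))
    for _ in range(max_iter):
        for a in range(p):
            for b in range(p):
                G[a, b] = 0.0
        for j in range(k):
            wj = nj[j] / n
            W = wj * S[j]
            omega = np.linalg.eigvalsh(W)[p - 1]
            # G += (omega I - W) @ R @ diag(1/(d_j D_j))
            M = omega * np.eye(p) - W
            T = M @ R
            for a in range(p):
                for b in range(p):
                    G[a, b] += T[a, b] / (d[j] * D[j, b])
        U, sv, Vt = np.linalg.svd(G)
        R_new = U @ Vt
        delta = _rot_change(R, R_new)
        R = R_new
        if delta <= tol:
            break
    return R


@njit(cache=True)
def _scatter_objective(S, nj, d, D, R):
    k, p = D.shape
    tmp = np.empty(p)
    obj = 0.0
    for j in range(k):
        _quad_diag(R[j], S[j], tmp)
        s = 0.0
        ld = 0.0
        for a in range(p):
            s += tmp[a] / D[j, a]
            ld += np.log(D[j, a])
        obj += nj[j] * (p * np.log(d[j]) + ld + s / d[j])
    return obj


@njit(cache=True)
def _update_scatters(
    S, nj, c_det, c_shw, c_shb, rot,
    max_iter_scatter, max_iter_shape, max_iter_rotation,
    tol_scatter, tol_shape, tol_rotation,
    has_state, d_state, D_state, R_state,
    d, D, R, Sigma,
):
    """Full constrained scatter update; returns 0 ok / 1 degenerate."""
    k = S.shape[0]
    p = S.shape[1]
    # volume init from eigenvalues; rotation init per regime
    scale = 0.0
    for j in range(k):
        for a in range(p):
            scale += S[j, a, a]
    scale = max(scale / (k * p), 1e-300)
    for j in range(k):
        ev = np.linalg.eigvalsh(S[j])
        ok = True
        ld = 0.0
        for a in range(p):
            if ev[a] <= 0.0:
                ok = False
                break
            ld += np.log(ev[a])
        d[j] = np.exp(ld / p) if ok else 0.0
        if d[j] < 1e-12 * scale:
            d[j] = 1e-12 * scale
    if rot == ROT_V:
        for j in range(k):
            evj, Vj = np.linalg.eigh(S[j])
            for a in range(p):
                for b in range(p):
                    R[j, a, b] = Vj[a, p - 1 - b]
            _canon_signs(R[j])
    elif rot == ROT_I:
        for j in range(k):
            for a in range(p):
                for b in range(p):
                    R[j, a, b] = 1.0 if a == b else 0.0
    else:
        pooled = np.zeros((p, p))
        ntot = 0.0
        for j in range(k):
            ntot += nj[j]
        for j in range(k):
            w = nj[j] / (ntot * d[j])
            for a in range(p):
                for b in range(p):
                    pooled[a, b] += w * S[j, a, b]
        evp, Vp = np.linalg.eigh(pooled)
        Rc = np.empty((p, p))
        for a in range(p):
            for b in range(p):
                Rc[a, b] = Vp[a, p - 1 - b]
        _canon_signs(Rc)
        for j in range(k):
            for a in range(p):
                for b in range(p):
                    R[j, a, b] = Rc[a, b]

    d_prev = np.empty(k)
    D_prev = np.empty((k, p))
    R_prev = np.empty((k, p, p))
    first = True
    for _ in range(max_iter_scatter):
        st = _update_shapes(S, nj, d, R, c_shw, c_shb, rot, max_iter_shape, tol_shape, D)
        if st != 0:
            return 1
        st = _update_volumes(S, nj, D, R, c_det, d)
        if st != 0:
            return 1
        if rot == ROT_E and p > 1:
            Rc = _update_rotation_common(S, nj, d, D, R[0], max_iter_rotation, tol_rotation)
            for j in range(k):
                for a in range(p):
                    for b in range(p):
                        R[j, a, b] = Rc[a, b]
        if not first:
            delta = _rel_change(d_prev, d)
            dd = _rel_change(D_prev, D)
            if dd > delta:
                delta = dd
            for j in range(k):
                dr = _rot_change(R_prev[j], R[j])
                if dr > delta:
                    delta = dr
            if delta <= tol_scatter:
                break
        first = False
        d_prev[:] = d
        D_prev[:] = D
        R_prev[:] = R

    if has_state:
        if _scatter_objective(S, nj, d_state, D_state, R_state) < _scatter_objective(S, nj, d, D, R):
            d[:] = d_state
            D[:] = D_state
            R[:] = R_state
    if rot == ROT_V:
        tmp = np.empty(p)
        Rt = np.empty((p, p))
        for j in range(k):
            order = np.argsort(-D[j])
            for a in range(p):
                tmp[a] = D[j, order[a]]
                for r in range(p):
                    Rt[r, a] = R[j, r, order[a]]
            for a in range(p):
                D[j, a] = tmp[a]
                for r in range(p):
                    R[j, r, a] = Rt[r, a]
    for j in range(k):
        for a in range(p):
            for b in range(p):
                s = 0.0
                for l in range(p):
                    s += R[j, a, l] * D[j, l] * R[j, b, l]
                Sigma[j, a, b] = d[j] * s
    return 0


@njit(cache=True)
def run_start(
    X, pi0, mu0, cov0,
    c_det, c_shw, c_shb, rot, hard,
    max_iter, max_iter_scatter, max_iter_shape, max_iter_rotation,
    tol, tol_scatter, tol_shape, tol_rotation,
):
    """One full ECM start; mirrors the reference ``_run_start`` loop.

    Returns (status, pi, mu, cov, d, D, R, tau, labels, n_iter, converged,
    target, history, hist_len).
    """
    n, p = X.shape
    k = pi0.size
    pi = pi0.copy()
    mu = mu0.copy()
    cov = cov0.copy()
    d = np.empty(k)
    D = np.empty((k, p))
    R = np.empty((k, p, p))
    d_state = np.empty(k)
    D_state = np.empty((k, p))
    R_state = np.empty((k, p, p))
    has_state = False
    lw = np.empty((n, k))
    tau = np.empty((n, k))
    nj = np.empty(k)
    S = np.empty((k, p, p))
    history = np.empty(max_iter + 1)
    labels = np.empty(n, dtype=np.int64)
    pi_new = np.empty(k)
    mu_new = np.empty((k, p))
    Sigma = np.empty((k, p, p))
    n_iter = 0
    converged = False
    hist_len = 0
    mass_floor = max(1e-10, n * 1e-12)
    for n_iter in range(1, max_iter + 1):
        if _log_densities(X, pi, mu, cov, lw) != 0:
            return (1, pi, mu, cov, d, D, R, tau, labels, n_iter, False, -np.inf, history, hist_len)
        target = _e_step(lw, hard, tau)
        history[hist_len] = target
        hist_len += 1
        for j in range(k):
            nj[j] = 0.0
            for i in range(n):
                nj[j] += tau[i, j]
            if nj[j] < mass_floor:
                return (1, pi, mu, cov, d, D, R, tau, labels, n_iter, False, -np.inf, history, hist_len)
        _m_step(X, tau, pi_new, mu_new, nj, S)
        st = _update_scatters(
            S, nj, c_det, c_shw, c_shb, rot,
            max_iter_scatter, max_iter_shape, max_iter_rotation,
            tol_scatter, tol_shape, tol_rotation,
            has_state, d_state, D_state, R_state,
            d, D, R, Sigma,
        )
        if st != 0:
            return (1, pi, mu, cov, d, D, R, tau, labels, n_iter, False, -np.inf, history, hist_len)
        d_state[:] = d
        D_state[:] = D
        R_state[:] = R
        has_state = True
        delta = _rel_change(pi, pi_new)
        dm = _rel_change(mu, mu_new)
        if dm > delta:
            delta = dm
        dc = _rel_change(cov, Sigma)
        if dc > delta:
            delta = dc
        pi[:] = pi_new
        mu[:] = mu_new
        cov[:] = Sigma
        if delta <= tol:
            converged = True
            break
    if _log_densities(X, pi, mu, cov, lw) != 0:
        return (1, pi, mu, cov, d, D, R, tau, labels, n_iter, False, -np.inf, history, hist_len)
    target = _e_step(lw, hard, tau)
    history[hist_len] = target
    hist_len += 1
    for i in range(n):
        mx = lw[i, 0]
        arg = 0
        for j in range(1, k):
            if lw[i, j] > mx:
                mx = lw[i, j]
                arg = j
        labels[i] = arg
    return (0, pi, mu, cov, d, D, R, tau, labels, n_iter, converged, target, history, hist_len)
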