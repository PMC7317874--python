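"""Numba kernels for voxel-wise MM fitting.

The MM objective is evaluated millions of times in the simulation
studies, so the GPD sphere sum, the SSE objective and the bounded
Nelder-Mead search are compiled. The sphere attenuation here is
algebraically identical to :func:`mmtid.models.restricted_sphere_attenuation`
(a unit test holds the two implementations to 1e-12).

Bounds are enforced by running an unconstrained simplex in a
sigmoid-transformed space: x = lo + (hi - lo) / (1 + exp(-u)).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .protocol import GAMMA_H

# Nelder-Mead coefficients (standard simplex: reflection, expansion,
# contraction, shrink) and initial simplex step in transformed space.
_RHO, _CHI, _PSI, _SIGMA = 1.0, 2.0, 0.5, 0.5
_U_STEP = 0.35


def protocol_arrays(protocol):
    """Pack a protocol into the flat arrays the kernels consume."""
    G = np.array([m.G for m in protocol]) * 1e-3            # T/m
    pref2 = 2.0 * GAMMA_H**2 * G**2                         # 2 gamma^2 G^2
    delta_eff_s = protocol.measurements[0].delta_eff * 1e-3
    deltas = np.array([m.Delta for m in protocol]) * 1e-3   # s
    u_delta = np.unique(deltas)
    idx_delta = np.searchsorted(u_delta, deltas)
    b1e3 = protocol.b_values * 1e-3                          # b * 1e-3 (for D in um^2/ms)
    return pref2, idx_delta.astype(np.int64), u_delta, delta_eff_s, b1e3


@njit(cache=True)
def _sphere_log_coeff(R_um, Di, mu, d_s, u_delta, out):
    """out[k] = sum_m w_m * bracket(lam_m; d, u_delta[k]) in SI (m^2 s^2).

    ln A(measurement j) = -pref2_j * out[idx_delta_j].
    """
    R = R_um * 1e-6
    D = Di * 1e-9
    n = mu.shape[0]
    for k in range(u_delta.shape[0]):
        out[k] = 0.0
    for i in range(n):
        m2 = mu[i] * mu[i]
        lam = D * m2 / (R * R)
        w = R**6 / (D * D * mu[i] ** 6 * (m2 - 2.0))
        eld = np.exp(-lam * d_s)
        for k in range(u_delta.shape[0]):
            DD = u_delta[k]
            br = (
                2.0 * lam * d_s - 2.0 + 2.0 * eld
                + 2.0 * np.exp(-lam * DD)
                - np.exp(-lam * (DD - d_s))
                - np.exp(-lam * (DD + d_s))
            )
            out[k] += w * br


@njit(cache=True)
def mm_predict(R, Di, De, fi, pref2, idx_delta, u_delta, d_s, b1e3, mu, out):
    """MM signal S_j = fi*A_sphere_j + (1-fi)*exp(-b_j De) for all j."""
    coeff = np.empty(u_delta.shape[0])
    _sphere_log_coeff(R, Di, mu, d_s, u_delta, coeff)
    for j in range(pref2.shape[0]):
        a = np.exp(-pref2[j] * coeff[idx_delta[j]])
        out[j] = fi * a + (1.0 - fi) * np.exp(-b1e3[j] * De)


@njit(cache=True)
def _mm_sse(x, fix_di, di_val, y, mask, pref2, idx_delta, u_delta, d_s, b1e3, mu):
    if fix_di:
        R, Di, De, fi = x[0], di_val, x[1], x[2]
    else:
        R, Di, De, fi = x[0], x[1], x[2], x[3]
    coeff = np.empty(u_delta.shape[0])
    _sphere_log_coeff(R, Di, mu, d_s, u_delta, coeff)
    sse = 0.0
    for j in range(pref2.shape[0]):
        if not mask[j]:
            continue
        a = np.exp(-pref2[j] * coeff[idx_delta[j]])
        r = fi * a + (1.0 - fi) * np.exp(-b1e3[j] * De) - y[j]
        sse += r * r
    return sse


@njit(cache=True)
def _to_x(u, lo, hi, x):
    for i in range(u.shape[0]):
        x[i] = lo[i] + (hi[i] - lo[i]) / (1.0 + np.exp(-u[i]))


@njit(cache=True)
def _nm_bounded(u0, lo, hi, fix_di, di_val, y, mask,
                pref2, idx_delta, u_delta, d_s, b1e3, mu,
                xatol, fatol, maxfev):
    """Nelder-Mead on the sigmoid-transformed space. Returns (x, f, nfev, conv)."""
    m = u0.shape[0]
    np1 = m + 1
    U = np.empty((np1, m))
    X = np.empty((np1, m))
    F = np.empty(np1)
    xb = np.empty(m)
    for i in range(m):
        U[0, i] = u0[i]
    for v in range(1, np1):
        for i in range(m):
            U[v, i] = u0[i]
        U[v, v - 1] += _U_STEP
    nfev = 0
    for v in range(np1):
        _to_x(U[v], lo, hi, X[v])
        F[v] = _mm_sse(X[v], fix_di, di_val, y, mask,
                       pref2, idx_delta, u_delta, d_s, b1e3, mu)
        nfev += 1

    order = np.argsort(F)
    converged = False
    xr = np.empty(m)
    xe = np.empty(m)
    xc = np.empty(m)
    cen = np.empty(m)
    while nfev < maxfev:
        # sort vertices
        order = np.argsort(F)
        U, X, F = U[order], X[order], F[order]
        # convergence: parameter spread in original space + objective spread
        xspread = 0.0
        for i in range(m):
            cmin = X[0, i]
            cmax = X[0, i]
            for v in range(1, np1):
                if X[v, i] < cmin:
                    cmin = X[v, i]
                if X[v, i] > cmax:
                    cmax = X[v, i]
            if cmax - cmin > xspread:
                xspread = cmax - cmin
        fspread = F[np1 - 1] - F[0]
        if xspread <= xatol and fspread <= fatol:
            converged = True
            break
        # centroid of all but worst
        for i in range(m):
            s = 0.0
            for v in range(m):
                s += U[v, i]
            cen[i] = s / m
        # reflection
        for i in range(m):
            xr[i] = cen[i] + _RHO * (cen[i] - U[np1 - 1, i])
        _to_x(xr, lo, hi, xb)
        fr = _mm_sse(xb, fix_di, di_val, y, mask,
                     pref2, idx_delta, u_delta, d_s, b1e3, mu)
        nfev += 1
        if fr < F[0]:
            # expansion
            for i in range(m):
                xe[i] = cen[i] + _RHO * _CHI * (cen[i] - U[np1 - 1, i])
            _to_x(xe, lo, hi, xb)
            fe = _mm_sse(xb, fix_di, di_val, y, mask,
                         pref2, idx_delta, u_delta, d_s, b1e3, mu)
            nfev += 1
            if fe < fr:
                U[np1 - 1] = xe
                F[np1 - 1] = fe
            else:
                U[np1 - 1] = xr
                F[np1 - 1] = fr
            _to_x(U[np1 - 1], lo, hi, X[np1 - 1])
            continue
        if fr < F[np1 - 2]:
            U[np1 - 1] = xr
            F[np1 - 1] = fr
            _to_x(U[np1 - 1], lo, hi, X[np1 - 1])
            continue
        # contraction
        if fr < F[np1 - 1]:
            for i in range(m):
                xc[i] = cen[i] + _PSI * _RHO * (cen[i] - U[np1 - 1, i])
        else:
            for i in range(m):
                xc[i] = cen[i] - _PSI * (cen[i] - U[np1 - 1, i])
        _to_x(xc, lo, hi, xb)
        fc = _mm_sse(xb, fix_di, di_val, y, mask,
                     pref2, idx_delta, u_delta, d_s, b1e3, mu)
        nfev += 1
        if fc < min(fr, F[np1 - 1]):
            U[np1 - 1] = xc
            F[np1 - 1] = fc
            _to_x(U[np1 - 1], lo, hi, X[np1 - 1])
            continue
        # shrink toward best
        for v in range(1, np1):
            for i in range(m):
                U[v, i] = U[0, i] + _SIGMA * (U[v, i] - U[0, i])
            _to_x(U[v], lo, hi, X[v])
            F[v] = _mm_sse(X[v], fix_di, di_val, y, mask,
                           pref2, idx_delta, u_delta, d_s, b1e3, mu)
            nfev += 1

    order = np.argsort(F)
    best = order[0]
    return X[best].copy(), F[best], nfev, converged


@njit(cache=True)
def fit_mm_multistart(starts, lo, hi, fix_di, di_val, y, mask,
                      pref2, idx_delta, u_delta, d_s, b1e3, mu,
                      xatol, fatol, maxfev):
    """Best-of-starts bounded Nelder-Mead. ``starts`` are in original units.

    Returns (x_best, sse_best, any_converged); the best objective value is
    non-increasing in the number of rows of ``starts``.
    """
    m = lo.shape[0]
    u0 = np.empty(m)
    best_f = np.inf
    best_x = np.empty(m)
    any_conv = False
    for s in range(starts.shape[0]):
        for i in range(m):
            frac = (starts[s, i] - lo[i]) / (hi[i] - lo[i])
            if frac < 1e-9:
                frac = 1e-9
            if frac > 1.0 - 1e-9:
                frac = 1.0 - 1e-9
            u0[i] = np.log(frac / (1.0 - frac))
        x, f, nfev, conv = _nm_bounded(
            u0, lo, hi, fix_di, di_val, y, mask,
            pref2, idx_delta, u_delta, d_s, b1e3, mu, xatol, fatol, maxfev
        )
        if f < best_f:
            best_f = f
            best_x[:] = x
            any_conv = conv
    return best_x, best_f, any_conv
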