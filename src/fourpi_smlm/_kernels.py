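"""Compiled kernels for spline evaluation and emitter fitting.

The spline coefficient tensor S has shape (C, NI, NJ, NK, 64) with flat
polynomial index (m*4 + n)*4 + o for powers (m, n, o) of the normalized
(x, y, z) cell coordinates.  The imaging model per pixel and channel is
mu = b + A * f_S(px - x0, py - y0, z0, c).

Two objectives share one Levenberg-Marquardt loop:

* mode 0 — unweighted least squares: merit = sum (mu - d)^2;
* mode 1 — Poisson maximum likelihood by damped Fisher scoring: the normal
  equations are weighted by 1/mu and the merit is the Poisson deviance
  2 * sum [mu - d + d ln(d / mu)], which is >= 0, vanishes for a perfect
  fit and plays the role of the Chi-square goodness-of-fit value.
"""

import numpy as np
from numba import njit

MODE_LSQ = 0
MODE_MLE = 1

_MU_FLOOR = 1e-9


@njit(cache=True)
def _basis_1d(s):
    b = np.empty(4)
    db = np.empty(4)
    b[0] = 1.0
    b[1] = s
    b[2] = s * s
    b[3] = s * s * s
    db[0] = 0.0
    db[1] = 1.0
    db[2] = 2.0 * s
    db[3] = 3.0 * s * s
    return b, db


@njit(cache=True)
def _locate(v, k0, dk, ncells):
    """Cell index and normalized coordinate for one axis (clamped)."""
    t = (v - k0) / dk
    i = int(np.floor(t))
    if i < 0:
        i = 0
    elif i > ncells - 1:
        i = ncells - 1
    return i, t - i


@njit(cache=True)
def _merit_terms(
    S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, p, jtj, jtr,
    with_jac, mode,
):
    """Merit value (and optionally normal equations) for one ROI image.

    data has shape (C, ny, nx); p = (x0, y0, z0, A, b).  Fills jtj (5,5)
    and jtr (5,) when with_jac is True.  Returns the merit (sum of squared
    residuals, or Poisson deviance in MLE mode).
    """
    nc, ni, nj, nk = S.shape[0], S.shape[1], S.shape[2], S.shape[3]
    ny = pix_y.shape[0]
    nx = pix_x.shape[0]
    x0, y0, z0, A, b = p[0], p[1], p[2], p[3], p[4]
    kz, sz = _locate(z0, z0k, dzk, nk)
    merit = 0.0
    if with_jac:
        for a in range(5):
            jtr[a] = 0.0
            for bb in range(5):
                jtj[a, bb] = 0.0
    J = np.empty(5)
    for iy in range(ny):
        jy, sy = _locate(pix_y[iy] - y0, y0k, dyk, nj)
        by, dby = _basis_1d(sy)
        for ix in range(nx):
            jx, sx = _locate(pix_x[ix] - x0, x0k, dxk, ni)
            bx, dbx = _basis_1d(sx)
            for c in range(nc):
                cell = S[c, jx, jy, kz]
                v = 0.0
                gx = 0.0
                gy = 0.0
                gz = 0.0
                for m in range(4):
                    for n in range(4):
                        base = (m * 4 + n) * 4
                        c0 = cell[base]
                        c1 = cell[base + 1]
                        c2 = cell[base + 2]
                        c3 = cell[base + 3]
                        s0 = c0 + sz * (c1 + sz * (c2 + sz * c3))
                        s1 = c1 + sz * (2.0 * c2 + 3.0 * sz * c3)
                        bmn = bx[m] * by[n]
                        v += bmn * s0
                        gz += bmn * s1
                        gx += dbx[m] * by[n] * s0
                        gy += bx[m] * dby[n] * s0
                mu = b + A * v
                d = data[c, iy, ix]
                if mode == MODE_MLE:
                    mu_c = mu if mu > _MU_FLOOR else _MU_FLOOR
                    if d > 0.0:
                        merit += 2.0 * (mu_c - d + d * np.log(d / mu_c))
                    else:
                        merit += 2.0 * mu_c
                    w = 1.0 / mu_c
                    r = mu_c - d
                else:
                    r = mu - d
                    merit += r * r
                    w = 1.0
                if with_jac:
                    J[0] = -A * gx / dxk
                    J[1] = -A * gy / dyk
                    J[2] = A * gz / dzk
                    J[3] = v
                    J[4] = 1.0
                    for a in range(5):
                        jtr[a] += w * J[a] * r
                        for bb in range(a, 5):
                            jtj[a, bb] += w * J[a] * J[bb]
    if with_jac:
        for a in range(5):
            for bb in range(a):
                jtj[a, bb] = jtj[bb, a]
    return merit


@njit(cache=True)
def _reflect(v, lo, hi):
    if hi <= lo:
        return 0.5 * (lo + hi)
    span = hi - lo
    # reflect once, then clamp (larger excursions are pathological anyway)
    if v < lo:
        v = lo + min(lo - v, span)
    elif v > hi:
        v = hi - min(v - hi, span)
    if v < lo:
        v = lo
    elif v > hi:
        v = hi
    return v


@njit(cache=True)
def _param_bounds(x0k, dxk, ni, y0k, dyk, nj, z0k, dzk, nk, pix_x, pix_y):
    """Bounds keeping every evaluated point inside the spline support."""
    xmin = x0k
    xmax = x0k + ni * dxk
    ymin = y0k
    ymax = y0k + nj * dyk
    zmin = z0k
    zmax = z0k + nk * dzk
    # px - x0 in [xmin, xmax] for all pixels
    x_lo = pix_x[-1] - xmax
    x_hi = pix_x[0] - xmin
    y_lo = pix_y[-1] - ymax
    y_hi = pix_y[0] - ymin
    eps = 1e-9
    return (
        x_lo + eps,
        x_hi - eps,
        y_lo + eps,
        y_hi - eps,
        zmin + eps,
        zmax - eps,
    )


@njit(cache=True)
def lm_fit(
    S,
    x0k,
    dxk,
    y0k,
    dyk,
    z0k,
    dzk,
    pix_x,
    pix_y,
    data,
    p_init,
    max_iter,
    rtol,
    mode,
):
    """Damped (Levenberg-Marquardt) fit of one ROI image.

    Returns (params, merit, converged, n_iter).  Position parameters are
    reflected back into the spline support after every step — the cubic
    polynomial is never extrapolated.
    """
    ni = S.shape[1]
    nj = S.shape[2]
    nk = S.shape[3]
    x_lo, x_hi, y_lo, y_hi, z_lo, z_hi = _param_bounds(
        x0k, dxk, ni, y0k, dyk, nj, z0k, dzk, nk, pix_x, pix_y
    )
    p = p_init.copy()
    p[0] = _reflect(p[0], x_lo, x_hi)
    p[1] = _reflect(p[1], y_lo, y_hi)
    p[2] = _reflect(p[2], z_lo, z_hi)
    jtj = np.empty((5, 5))
    jtr = np.empty(5)
    merit = _merit_terms(
        S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, p, jtj, jtr,
        True, mode,
    )
    lam = 1e-3
    converged = False
    it = 0
    mat = np.empty((5, 5))
    for it in range(max_iter):
        for a in range(5):
            for bb in range(5):
                mat[a, bb] = jtj[a, bb]
            d = jtj[a, a]
            if d <= 0.0:
                d = 1e-12
            mat[a, a] = d * (1.0 + lam)
        dp = np.linalg.solve(mat, -jtr)
        p_new = p + dp
        p_new[0] = _reflect(p_new[0], x_lo, x_hi)
        p_new[1] = _reflect(p_new[1], y_lo, y_hi)
        p_new[2] = _reflect(p_new[2], z_lo, z_hi)
        merit_new = _merit_terms(
            S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, p_new,
            jtj, jtr, False, mode,
        )
        if merit_new <= merit:
            improvement = merit - merit_new
            p = p_new
            merit = merit_new
            lam = max(lam * 0.3, 1e-12)
            done = improvement <= rtol * max(merit, 1e-30)
            _merit_terms(
                S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, p,
                jtj, jtr, True, mode,
            )
            if done:
                converged = True
                break
        else:
            lam *= 10.0
            if lam > 1e10:
                break
    return p, merit, converged, it + 1


@njit(cache=True)
def _init_amplitude(
    S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, x_init, y_init, z_init
):
    """Linear least-squares (A, b) given a trial position."""
    jtj = np.empty((5, 5))
    jtr = np.empty(5)
    p = np.empty(5)
    p[0] = x_init
    p[1] = y_init
    p[2] = z_init
    p[3] = 1.0
    p[4] = 0.0
    # unweighted terms with A=1, b=0: the (A, b) rows of jtj/jtr give the
    # sums Σf², Σf, Σf·d, Σd needed for the 2-parameter linear solve
    _merit_terms(
        S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, p, jtj, jtr,
        True, MODE_LSQ,
    )
    sff = jtj[3, 3]
    sf = jtj[3, 4]
    n = jtj[4, 4]
    # jtr = J^T (mu - data) with mu = f  → Σf·d = Σf² - jtr_A, Σd = Σf - jtr_b
    sfd = sff - jtr[3]
    sd = sf - jtr[4]
    det = sff * n - sf * sf
    if det <= 1e-12:
        return 1.0, 0.0
    A = (sfd * n - sf * sd) / det
    b = (sd * sff - sf * sfd) / det
    if A < 1e-6:
        A = 1e-6
    if b < 0.0:
        b = 0.0
    return A, b


@njit(cache=True)
def fit_multistart(
    S,
    x0k,
    dxk,
    y0k,
    dyk,
    z0k,
    dzk,
    pix_x,
    pix_y,
    data,
    x_init,
    y_init,
    z_starts,
    max_iter,
    rtol,
    mode,
):
    """Multi-start fit over a grid of initial z offsets.

    Returns (best_params, best_chi2, best_converged, n_starts,
    start_chi2s, start_zs) where start_chi2s/start_zs record the converged
    merit and z of every start (inf / nan for failed starts).  Ties in the
    merit break toward smaller |z| (closest to focus).
    """
    n_starts = z_starts.shape[0]
    best_p = np.full(5, np.nan)
    best_chi2 = np.inf
    best_conv = False
    start_chi2s = np.full(n_starts, np.inf)
    start_zs = np.full(n_starts, np.nan)
    for s in range(n_starts):
        A0, b0 = _init_amplitude(
            S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data,
            x_init, y_init, z_starts[s],
        )
        p0 = np.empty(5)
        p0[0] = x_init
        p0[1] = y_init
        p0[2] = z_starts[s]
        p0[3] = A0
        p0[4] = b0
        p, chi2, conv, _ = lm_fit(
            S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, data, p0,
            max_iter, rtol, mode,
        )
        if conv:
            start_chi2s[s] = chi2
            start_zs[s] = p[2]
        better = False
        if conv and not best_conv:
            better = True
        elif conv == best_conv:
            if chi2 < best_chi2 * (1.0 - 1e-12):
                better = True
            elif abs(chi2 - best_chi2) <= 1e-12 * max(chi2, 1.0) and abs(
                p[2]
            ) < abs(best_p[2]):
                better = True
        if better:
            best_p = p
            best_chi2 = chi2
            best_conv = conv
    return best_p, best_chi2, best_conv, n_starts, start_chi2s, start_zs


@njit(cache=True)
def fit_batch(
    S,
    x0k,
    dxk,
    y0k,
    dyk,
    z0k,
    dzk,
    pix_x,
    pix_y,
    images,
    xy_inits,
    z_starts,
    max_iter,
    rtol,
    mode,
):
    """Multi-start fit of a batch of ROI images (N, C, ny, nx)."""
    n = images.shape[0]
    params = np.empty((n, 5))
    chi2s = np.empty(n)
    conv = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        p, c2, cv, _, _, _ = fit_multistart(
            S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, images[i],
            xy_inits[i, 0], xy_inits[i, 1], z_starts, max_iter, rtol, mode,
        )
        params[i] = p
        chi2s[i] = c2
        conv[i] = cv
    return params, chi2s, conv


@njit(cache=True)
def refit_batch(
    S,
    x0k,
    dxk,
    y0k,
    dyk,
    z0k,
    dzk,
    pix_x,
    pix_y,
    images,
    p_inits,
    z_offsets,
    max_iter,
    rtol,
    mode,
):
    """Warm-started fits: each image restarts from its previous solution,
    optionally displaced by a few z offsets (to cover fringe swaps when the
    model phase changes).  Returns the lowest-merit converged result.
    """
    n = images.shape[0]
    params = np.empty((n, 5))
    chi2s = np.full(n, np.inf)
    conv = np.zeros(n, dtype=np.bool_)
    z_lo = z0k
    z_hi = z0k + S.shape[3] * dzk
    for i in range(n):
        best_p = np.full(5, np.nan)
        best_c2 = np.inf
        best_cv = False
        for s in range(z_offsets.shape[0]):
            z_try = p_inits[i, 2] + z_offsets[s]
            if z_try <= z_lo or z_try >= z_hi:
                continue
            p0 = p_inits[i].copy()
            p0[2] = z_try
            p, c2, cv, _ = lm_fit(
                S, x0k, dxk, y0k, dyk, z0k, dzk, pix_x, pix_y, images[i],
                p0, max_iter, rtol, mode,
            )
            if (cv and not best_cv) or (cv == best_cv and c2 < best_c2):
                best_p = p
                best_c2 = c2
                best_cv = cv
        params[i] = best_p
        chi2s[i] = best_c2
        conv[i] = best_cv
    return params, chi2s, conv
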