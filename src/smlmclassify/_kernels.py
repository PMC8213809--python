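"""Numba kernels for the 2D pairwise-registration hot path.

The all-to-all registration dominates total runtime (N(N−1)/2 pairs,
each a 3-parameter optimization whose objective is a double sum over
localization pairs), so the inner loops live here as nopython kernels.

Numerical notes
---------------
* The GMM-overlap objective drops terms with exponent < −10 (relative
  contribution < 5e-5); this only affects the *search* objective.
* The Bhattacharyya similarity is always evaluated with the full,
  cutoff-free double sum so scores match the written form to machine
  precision.
* The Nelder–Mead works on (angle, tx/s, ty/s) with translations scaled
  by ``tscale`` so the simplex is well conditioned across units.
"""

import numpy as np
from numba import njit

_GMM_CUT = 10.0  # drop exp(arg) terms with arg < -10 in the search objective
_EXP_NT = 4096
# linear-interpolation table for exp on [-10, 0]: relative error < 1e-6,
# used only inside the search objective (the similarity metric is exact)
_EXP_TAB = np.exp(np.linspace(-10.0, 0.0, _EXP_NT + 1))
_EXP_SCALE = _EXP_NT / _GMM_CUT


@njit(cache=False, fastmath=True)
def gmm_sum_2d(ax, ay, bx, by, inv4s2, ct, st, tx, ty, buf):
    """Sum of exp(−|r_a − T r_b|² / 4s²) over all localization pairs."""
    acc = 0.0
    cutd = _GMM_CUT / inv4s2
    n = ax.shape[0]
    for j in range(bx.shape[0]):
        xb = ct * bx[j] - st * by[j] + tx
        yb = st * bx[j] + ct * by[j] + ty
        for i in range(n):
            dx = ax[i] - xb
            dy = ay[i] - yb
            buf[i] = dx * dx + dy * dy
        for i in range(n):
            if buf[i] < cutd:
                p = buf[i] * inv4s2 * _EXP_SCALE
                k = int(p)
                f = p - k
                acc += _EXP_TAB[_EXP_NT - k] * (1.0 - f) \
                    + _EXP_TAB[_EXP_NT - k - 1] * f
    return acc


@njit(cache=False, fastmath=True)
def bhat_sum_2d(ax, ay, as2, bx, by, bs2, ct, st, tx, ty, buf, vbuf):
    """Exact double sum of exp(−½ d²/(σa²+σb²))/(σa²+σb²), no cutoff."""
    acc = 0.0
    n = ax.shape[0]
    for j in range(bx.shape[0]):
        xb = ct * bx[j] - st * by[j] + tx
        yb = st * bx[j] + ct * by[j] + ty
        s2b = bs2[j]
        for i in range(n):
            v = as2[i] + s2b
            dx = ax[i] - xb
            dy = ay[i] - yb
            buf[i] = -0.5 * (dx * dx + dy * dy) / v
            vbuf[i] = 1.0 / v
        for i in range(n):
            acc += np.exp(buf[i]) * vbuf[i]
    return acc / (ax.shape[0] * bx.shape[0])


@njit(cache=False, fastmath=True)
def nm_maximize_2d(ax, ay, bx, by, inv4s2, theta0, tscale, xatol, frtol, maxfev, buf):
    """Nelder–Mead maximization of the GMM overlap over (θ, tx, ty).

    Starts at rotation ``theta0`` with the translation that aligns the
    two centroids under that rotation.  Returns (θ, tx, ty, value, nfev).
    """
    sim = np.empty((4, 3))
    fv = np.empty(4)
    cax = np.mean(ax)
    cay = np.mean(ay)
    cbx = np.mean(bx)
    cby = np.mean(by)
    ct0 = np.cos(theta0)
    st0 = np.sin(theta0)
    sim[0, 0] = theta0
    sim[0, 1] = (cax - (ct0 * cbx - st0 * cby)) / tscale
    sim[0, 2] = (cay - (st0 * cbx + ct0 * cby)) / tscale
    for k in range(3):
        for c in range(3):
            sim[k + 1, c] = sim[0, c]
    sim[1, 0] += 0.25
    sim[2, 1] += 1.0
    sim[3, 2] += 1.0
    nfev = 0
    for k in range(4):
        fv[k] = -gmm_sum_2d(ax, ay, bx, by, inv4s2, np.cos(sim[k, 0]),
                            np.sin(sim[k, 0]), sim[k, 1] * tscale,
                            sim[k, 2] * tscale, buf)
        nfev += 1
    while nfev < maxfev:
        order = np.argsort(fv)
        sim = sim[order]
        fv = fv[order]
        msize = 0.0
        for k in range(1, 4):
            for c in range(3):
                d = abs(sim[k, c] - sim[0, c])
                if d > msize:
                    msize = d
        if msize < xatol and abs(fv[3] - fv[0]) <= frtol * max(1e-300, abs(fv[0])):
            break
        cen0 = (sim[0, 0] + sim[1, 0] + sim[2, 0]) / 3.0
        cen1 = (sim[0, 1] + sim[1, 1] + sim[2, 1]) / 3.0
        cen2 = (sim[0, 2] + sim[1, 2] + sim[2, 2]) / 3.0
        xr0 = 2.0 * cen0 - sim[3, 0]
        xr1 = 2.0 * cen1 - sim[3, 1]
        xr2 = 2.0 * cen2 - sim[3, 2]
        fr = -gmm_sum_2d(ax, ay, bx, by, inv4s2, np.cos(xr0), np.sin(xr0),
                         xr1 * tscale, xr2 * tscale, buf)
        nfev += 1
        if fr < fv[0]:
            xe0 = 3.0 * cen0 - 2.0 * sim[3, 0]
            xe1 = 3.0 * cen1 - 2.0 * sim[3, 1]
            xe2 = 3.0 * cen2 - 2.0 * sim[3, 2]
            fe = -gmm_sum_2d(ax, ay, bx, by, inv4s2, np.cos(xe0), np.sin(xe0),
                             xe1 * tscale, xe2 * tscale, buf)
            nfev += 1
            if fe < fr:
                sim[3, 0] = xe0
                sim[3, 1] = xe1
                sim[3, 2] = xe2
                fv[3] = fe
            else:
                sim[3, 0] = xr0
                sim[3, 1] = xr1
                sim[3, 2] = xr2
                fv[3] = fr
        elif fr < fv[2]:
            sim[3, 0] = xr0
            sim[3, 1] = xr1
            sim[3, 2] = xr2
            fv[3] = fr
        else:
            if fr < fv[3]:
                xc0 = cen0 + 0.5 * (xr0 - cen0)
                xc1 = cen1 + 0.5 * (xr1 - cen1)
                xc2 = cen2 + 0.5 * (xr2 - cen2)
            else:
                xc0 = cen0 + 0.5 * (sim[3, 0] - cen0)
                xc1 = cen1 + 0.5 * (sim[3, 1] - cen1)
                xc2 = cen2 + 0.5 * (sim[3, 2] - cen2)
            fc = -gmm_sum_2d(ax, ay, bx, by, inv4s2, np.cos(xc0), np.sin(xc0),
                             xc1 * tscale, xc2 * tscale, buf)
            nfev += 1
            if fc < min(fr, fv[3]):
                sim[3, 0] = xc0
                sim[3, 1] = xc1
                sim[3, 2] = xc2
                fv[3] = fc
            else:
                for k in range(1, 4):
                    for c in range(3):
                        sim[k, c] = sim[0, c] + 0.5 * (sim[k, c] - sim[0, c])
                    fv[k] = -gmm_sum_2d(ax, ay, bx, by, inv4s2,
                                        np.cos(sim[k, 0]), np.sin(sim[k, 0]),
                                        sim[k, 1] * tscale, sim[k, 2] * tscale,
                                        buf)
                    nfev += 1
    best = 0
    for k in range(1, 4):
        if fv[k] < fv[best]:
            best = k
    return sim[best, 0], sim[best, 1] * tscale, sim[best, 2] * tscale, -fv[best], nfev


@njit(cache=False, fastmath=True)
def register_pair_2d(ax, ay, as2, bx, by, bs2, scale_nm, n_init,
                     xatol, frtol, maxfev, buf, vbuf):
    """Multi-start registration of particle b onto particle a.

    Runs ``n_init`` Nelder–Mead searches of the GMM overlap from angles
    uniform in [0, 2π), then evaluates the Bhattacharyya similarity at
    each optimum and keeps the transform with the highest similarity.

    Returns (θ, tx, ty, best_S, best_gmm_sum, total_nfev).
    """
    inv4s2 = 1.0 / (4.0 * scale_nm * scale_nm)
    tscale = max(scale_nm, 2.0)
    best_s = -1.0
    best_g = -1.0
    bth = 0.0
    btx = 0.0
    bty = 0.0
    nfev_tot = 0
    for k in range(n_init):
        th0 = 2.0 * np.pi * k / n_init
        th, tx, ty, g, nf = nm_maximize_2d(ax, ay, bx, by, inv4s2, th0,
                                           tscale, xatol, frtol, maxfev, buf)
        nfev_tot += nf
        s = bhat_sum_2d(ax, ay, as2, bx, by, bs2, np.cos(th), np.sin(th),
                        tx, ty, buf, vbuf)
        if s > best_s:
            best_s = s
            bth = th
            btx = tx
            bty = ty
        if g > best_g:
            best_g = g
    return bth, btx, bty, best_s, best_g, nfev_tot


@njit(cache=False, fastmath=True)
def all_pairs_2d(X, Y, S2, off, scale_nm, n_init, xatol, frtol, maxfev,
                 S, T, a_lo, a_hi):
    """All-to-all registration for particle rows in [a_lo, a_hi).

    Particles are packed flat (X, Y, S2 with offsets ``off``).  Fills the
    symmetric similarity matrix ``S`` and the transform parameters
    ``T[a, b] = (θ, tx, ty)`` mapping particle b onto particle a, for
    a < b.  Pairs where either particle has < 3 localizations are scored
    at the identity transform (a 3-parameter pose is under-determined).
    The row range allows chunked calls for progress reporting; results
    are independent of the chunking.
    """
    nmax = 0
    N = off.shape[0] - 1
    for a in range(N):
        if off[a + 1] - off[a] > nmax:
            nmax = off[a + 1] - off[a]
    buf = np.empty(nmax)
    vbuf = np.empty(nmax)
    for a in range(a_lo, a_hi):
        ax = X[off[a]:off[a + 1]]
        ay = Y[off[a]:off[a + 1]]
        as2 = S2[off[a]:off[a + 1]]
        for b in range(a + 1, N):
            bx = X[off[b]:off[b + 1]]
            by = Y[off[b]:off[b + 1]]
            bs2 = S2[off[b]:off[b + 1]]
            if ax.shape[0] < 3 or bx.shape[0] < 3:
                s = bhat_sum_2d(ax, ay, as2, bx, by, bs2, 1.0, 0.0,
                                0.0, 0.0, buf, vbuf)
                S[a, b] = s
                S[b, a] = s
                T[a, b, 0] = 0.0
                T[a, b, 1] = 0.0
                T[a, b, 2] = 0.0
            else:
                th, tx, ty, s, g, nf = register_pair_2d(
                    ax, ay, as2, bx, by, bs2, scale_nm, n_init,
                    xatol, frtol, maxfev, buf, vbuf)
                S[a, b] = s
                S[b, a] = s
                T[a, b, 0] = th
                T[a, b, 1] = tx
                T[a, b, 2] = ty
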