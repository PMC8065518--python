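"""Compiled inner loops for subset correlation and sub-pixel refinement.

Everything here operates on plain float64 arrays; the public API lives in
``dic_core``.  The bicubic sampler evaluates the same cubic B-spline
interpolant as ``scipy.ndimage.map_coordinates(order=3)`` on prefiltered
coefficients.  Because a displaced subset samples the interpolant on a
unit-spaced lattice, the fractional offset — hence the 4-tap spline weights
— is identical for every subset pixel, and sampling reduces to a separable
4x4 stencil convolution; value and both partial derivatives share the
row pass.  Callers guarantee that every sample position keeps the full
stencil inside the frame.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integer_search_points", "refine_points"]


@njit(cache=True, inline="always")
def _bspline_weights(t: float, w: np.ndarray, dw: np.ndarray) -> None:
    """Cubic B-spline weights (and derivatives) for nodes floor(x)-1 .. +2."""
    one = 1.0 - t
    w[0] = one * one * one / 6.0
    w[1] = 2.0 / 3.0 - t * t + 0.5 * t * t * t
    w[2] = 2.0 / 3.0 - one * one + 0.5 * one * one * one
    w[3] = t * t * t / 6.0
    dw[0] = -0.5 * one * one
    dw[1] = -2.0 * t + 1.5 * t * t
    dw[2] = 2.0 * one - 1.5 * one * one
    dw[3] = 0.5 * t * t


@njit(cache=True, fastmath=True)
def _sample_subset(
    coef: np.ndarray,
    cx: float,
    cy: float,
    u: float,
    v: float,
    half: int,
    g: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    tmp: np.ndarray,
    tmpd: np.ndarray,
    want_grad: bool,
) -> None:
    """Sample the interpolant (and gradients) over one displaced subset.

    ``g``/``gx``/``gy`` are flat (N^2,) outputs; ``tmp``/``tmpd`` are
    (N+3, N) scratch for the separable row pass.
    """
    N = 2 * half + 1
    wx = np.empty(4)
    dwx = np.empty(4)
    wy = np.empty(4)
    dwy = np.empty(4)
    x0 = cx + u
    y0 = cy + v
    bx = int(np.floor(x0))
    by = int(np.floor(y0))
    _bspline_weights(x0 - bx, wx, dwx)
    _bspline_weights(y0 - by, wy, dwy)
    left = bx - half - 1
    top = by - half - 1
    # row pass: tmp[r, i] = sum_ii wx[ii] * C[top+r, left+i+ii]
    for r in range(N + 3):
        crow = coef[top + r]
        if want_grad:
            for i in range(N):
                c0 = crow[left + i]
                c1 = crow[left + i + 1]
                c2 = crow[left + i + 2]
                c3 = crow[left + i + 3]
                tmp[r, i] = wx[0] * c0 + wx[1] * c1 + wx[2] * c2 + wx[3] * c3
                tmpd[r, i] = dwx[0] * c0 + dwx[1] * c1 + dwx[2] * c2 + dwx[3] * c3
        else:
            for i in range(N):
                tmp[r, i] = (
                    wx[0] * crow[left + i]
                    + wx[1] * crow[left + i + 1]
                    + wx[2] * crow[left + i + 2]
                    + wx[3] * crow[left + i + 3]
                )
    # column pass
    idx = 0
    for j in range(N):
        for i in range(N):
            g[idx] = (
                wy[0] * tmp[j, i]
                + wy[1] * tmp[j + 1, i]
                + wy[2] * tmp[j + 2, i]
                + wy[3] * tmp[j + 3, i]
            )
            if want_grad:
                gx[idx] = (
                    wy[0] * tmpd[j, i]
                    + wy[1] * tmpd[j + 1, i]
                    + wy[2] * tmpd[j + 2, i]
                    + wy[3] * tmpd[j + 3, i]
                )
                gy[idx] = (
                    dwy[0] * tmp[j, i]
                    + dwy[1] * tmp[j + 1, i]
                    + dwy[2] * tmp[j + 2, i]
                    + dwy[3] * tmp[j + 3, i]
                )
            idx += 1


@njit(cache=True, inline="always")
def _in_bounds(cx: float, cy: float, u: float, v: float, m: float, H: int, W: int) -> bool:
    return (
        cx + u - m >= 0.0
        and cx + u + m <= W - 1.0
        and cy + v - m >= 0.0
        and cy + v + m <= H - 1.0
    )


@njit(cache=True, fastmath=True)
def _cls_at(
    coef: np.ndarray,
    cx: float,
    cy: float,
    u: float,
    v: float,
    half: int,
    fh: np.ndarray,
    g: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    tmp: np.ndarray,
    tmpd: np.ndarray,
) -> float:
    """C_LS at (u, v); +inf if the current subset there is degenerate."""
    _sample_subset(coef, cx, cy, u, v, half, g, gx, gy, tmp, tmpd, False)
    n2 = g.size
    gm = 0.0
    for k in range(n2):
        gm += g[k]
    gm /= n2
    ss = 0.0
    for k in range(n2):
        d = g[k] - gm
        ss += d * d
    gnorm = np.sqrt(ss)
    if gnorm <= 0.0:
        return np.inf
    cls = 0.0
    for k in range(n2):
        d = fh[k] - (g[k] - gm) / gnorm
        cls += d * d
    return cls


@njit(cache=True, fastmath=True)
def refine_points(
    coef: np.ndarray,
    f_hat: np.ndarray,
    px: np.ndarray,
    py: np.ndarray,
    u_init: np.ndarray,
    v_init: np.ndarray,
    half: int,
    tol: float,
    max_iter: int,
    max_shift: float,
    deg_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Newton refinement of many points against one current frame.

    ``f_hat`` holds the unit-normalized mean-subtracted reference subsets
    (one row per point).  Returns (u, v, quality, converged, valid); the
    quality is the NCC coefficient at the solution.
    """
    n_pts = px.size
    N = 2 * half + 1
    n2 = N * N
    H, W = coef.shape
    m = half + 2.0  # interpolation stencil margin

    u_out = np.empty(n_pts)
    v_out = np.empty(n_pts)
    q_out = np.full(n_pts, np.nan)
    conv = np.zeros(n_pts, np.bool_)
    valid = np.ones(n_pts, np.bool_)

    g = np.empty(n2)
    gx = np.empty(n2)
    gy = np.empty(n2)
    g0 = np.empty(n2)
    tmp = np.empty((N + 3, N))
    tmpd = np.empty((N + 3, N))

    for p in range(n_pts):
        cx = px[p]
        cy = py[p]
        u = u_init[p]
        v = v_init[p]
        fh = f_hat[p]
        ok = True
        converged = False

        if not _in_bounds(cx, cy, u, v, m, H, W):
            valid[p] = False
            u_out[p] = np.nan
            v_out[p] = np.nan
            continue

        for _ in range(max_iter):
            _sample_subset(coef, cx, cy, u, v, half, g, gx, gy, tmp, tmpd, True)
            gm = 0.0
            gxm = 0.0
            gym = 0.0
            for k in range(n2):
                gm += g[k]
                gxm += gx[k]
                gym += gy[k]
            gm /= n2
            gxm /= n2
            gym /= n2
            ss = 0.0
            for k in range(n2):
                g0[k] = g[k] - gm
                ss += g0[k] * g0[k]
            gnorm = np.sqrt(ss)
            if gnorm < deg_floor:
                ok = False
                break

            # ghat = g0/gnorm; residual r = fh - ghat
            # d ghat/du = (I - ghat ghat^T)(gx - mean)/gnorm, same for v
            proj_x = 0.0
            proj_y = 0.0
            for k in range(n2):
                gh = g0[k] / gnorm
                proj_x += gh * (gx[k] - gxm)
                proj_y += gh * (gy[k] - gym)
            a11 = 0.0
            a12 = 0.0
            a22 = 0.0
            b1 = 0.0
            b2 = 0.0
            cls_cur = 0.0
            for k in range(n2):
                gh = g0[k] / gnorm
                jx = (gx[k] - gxm - proj_x * gh) / gnorm
                jy = (gy[k] - gym - proj_y * gh) / gnorm
                r = fh[k] - gh
                a11 += jx * jx
                a12 += jx * jy
                a22 += jy * jy
                b1 += jx * r
                b2 += jy * r
                cls_cur += r * r
            det = a11 * a22 - a12 * a12
            if not np.isfinite(det) or abs(det) < 1e-300:
                break
            du = (a22 * b1 - a12 * b2) / det
            dv = (a11 * b2 - a12 * b1) / det
            if not (np.isfinite(du) and np.isfinite(dv)):
                break

            # step damping: halve while C_LS increases (or the step leaves
            # the frame), up to 4 times
            step = 1.0
            nu = u + du
            nv = v + dv
            for _halve in range(5):
                if _in_bounds(cx, cy, nu, nv, m, H, W):
                    cls_new = _cls_at(coef, cx, cy, nu, nv, half, fh, g, gx, gy, tmp, tmpd)
                    if cls_new <= cls_cur + 1e-15:
                        break
                step *= 0.5
                nu = u + step * du
                nv = v + step * dv
            if not _in_bounds(cx, cy, nu, nv, m, H, W):
                break
            u = nu
            v = nv

            if (
                abs(u - u_init[p]) > max_shift
                or abs(v - v_init[p]) > max_shift
            ):
                break  # diverged outside the search window
            if np.hypot(step * du, step * dv) < tol:
                converged = True
                break

        if ok:
            # quality: NCC at the solution via interpolated sampling
            _sample_subset(coef, cx, cy, u, v, half, g, gx, gy, tmp, tmpd, False)
            gm = 0.0
            for k in range(n2):
                gm += g[k]
            gm /= n2
            ss = 0.0
            for k in range(n2):
                g0[k] = g[k] - gm
                ss += g0[k] * g0[k]
            gnorm = np.sqrt(ss)
            if gnorm < deg_floor:
                ok = False
            else:
                q = 0.0
                for k in range(n2):
                    q += fh[k] * g0[k] / gnorm
                q_out[p] = q

        if ok:
            u_out[p] = u
            v_out[p] = v
            conv[p] = converged
        else:
            valid[p] = False
            u_out[p] = np.nan
            v_out[p] = np.nan
            q_out[p] = np.nan
    return u_out, v_out, q_out, conv, valid


@njit(cache=True, fastmath=True)
def integer_search_points(
    ref: np.ndarray,
    cur: np.ndarray,
    sat1: np.ndarray,
    sat2: np.ndarray,
    pxi: np.ndarray,
    pyi: np.ndarray,
    half: int,
    radius: int,
    deg_ref: float,
    deg_cur: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive integer NCC search for many points.

    ``sat1``/``sat2`` are (H+1, W+1) summed-area tables of the current frame
    and its square, so candidate-subset sums cost O(1).  Ties at the peak
    (scores within 1e-9, absorbing summation round-off between genuinely
    equal candidates) break toward the smallest u^2+v^2, then smallest v,
    then smallest u.  Returns (u, v, peak_ncc, valid).
    """
    tie_eps = 1e-9
    n_pts = pxi.size
    N = 2 * half + 1
    n2 = N * N
    u_out = np.zeros(n_pts, np.int64)
    v_out = np.zeros(n_pts, np.int64)
    q_out = np.full(n_pts, np.nan)
    valid = np.ones(n_pts, np.bool_)
    t0 = np.empty((N, N))
    deg_ref_norm = deg_ref * N
    deg_cur_var = (deg_cur * N) ** 2

    for p in range(n_pts):
        x = pxi[p]
        y = pyi[p]
        tm = 0.0
        for j in range(N):
            for i in range(N):
                t0[j, i] = ref[y - half + j, x - half + i]
                tm += t0[j, i]
        tm /= n2
        tnorm2 = 0.0
        for j in range(N):
            for i in range(N):
                t0[j, i] -= tm
                tnorm2 += t0[j, i] * t0[j, i]
        tnorm = np.sqrt(tnorm2)
        if tnorm < deg_ref_norm:
            valid[p] = False
            continue

        best = -np.inf
        bu = 0
        bv = 0
        found = False
        for dv in range(-radius, radius + 1):
            ytop = y + dv - half
            for du in range(-radius, radius + 1):
                xleft = x + du - half
                s1 = (
                    sat1[ytop + N, xleft + N]
                    - sat1[ytop, xleft + N]
                    - sat1[ytop + N, xleft]
                    + sat1[ytop, xleft]
                )
                s2 = (
                    sat2[ytop + N, xleft + N]
                    - sat2[ytop, xleft + N]
                    - sat2[ytop + N, xleft]
                    + sat2[ytop, xleft]
                )
                var = s2 - s1 * s1 / n2
                if var < deg_cur_var or var <= 0.0:
                    continue
                cross = 0.0
                for j in range(N):
                    crow = cur[ytop + j]
                    trow = t0[j]
                    for i in range(N):
                        cross += trow[i] * crow[xleft + i]
                score = cross / (tnorm * np.sqrt(var))
                if not found or score > best + tie_eps:
                    best = score
                    bu = du
                    bv = dv
                    found = True
                elif score >= best - tie_eps:
                    r_new = du * du + dv * dv
                    r_old = bu * bu + bv * bv
                    if r_new < r_old or (
                        r_new == r_old
                        and (dv < bv or (dv == bv and du < bu))
                    ):
                        bu = du
                        bv = dv
                    if score > best:
                        best = score
        if not found:
            valid[p] = False
            continue
        u_out[p] = bu
        v_out[p] = bv
        q_out[p] = best
    return u_out, v_out, q_out, valid
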