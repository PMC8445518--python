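"""Numba kernels: incremental Siddon ray tracing, sensitivity, MLEM passes.

Flat voxel indexing is C-order over an (nx, ny, nz) image:
``flat = (ix * ny + iy) * nz + iz``.  All lengths are mm, times ps.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Speed of light in mm per ps.
C_MM_PER_PS = 0.299792458

_SQRT1_2 = 0.7071067811865476


@njit(cache=True)
def trace_ray(
    p0x, p0y, p0z, p1x, p1y, p1z,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    out_idx, out_len,
):
    """Incremental Siddon traversal of the segment p0->p1 through the grid.

    Fills ``out_idx`` (flat voxel indices) and ``out_len`` (intersection
    lengths, mm) and returns the number of voxels crossed.  Returns -1 for
    a degenerate (zero-length) ray.
    """
    ddx = p1x - p0x
    ddy = p1y - p0y
    ddz = p1z - p0z
    length = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
    if length == 0.0:
        return -1

    tmin = 0.0
    tmax = 1.0
    # clip against the three slab pairs
    if ddx != 0.0:
        t1 = (ox - p0x) / ddx
        t2 = (ox + nx * vx - p0x) / ddx
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif p0x < ox or p0x > ox + nx * vx:
        return 0
    if ddy != 0.0:
        t1 = (oy - p0y) / ddy
        t2 = (oy + ny * vy - p0y) / ddy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif p0y < oy or p0y > oy + ny * vy:
        return 0
    if ddz != 0.0:
        t1 = (oz - p0z) / ddz
        t2 = (oz + nz * vz - p0z) / ddz
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif p0z < oz or p0z > oz + nz * vz:
        return 0
    if tmin >= tmax:
        return 0

    tcur = tmin
    # entry voxel (clipped for boundary roundoff)
    px = p0x + ddx * tcur
    py = p0y + ddy * tcur
    pz = p0z + ddz * tcur
    ix = int(math.floor((px - ox) / vx))
    iy = int(math.floor((py - oy) / vy))
    iz = int(math.floor((pz - oz) / vz))
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz >= nz:
        iz = nz - 1

    inf = 1e300
    if ddx > 0.0:
        step_x, t_nx, dtx = 1, (ox + (ix + 1) * vx - p0x) / ddx, vx / abs(ddx)
    elif ddx < 0.0:
        step_x, t_nx, dtx = -1, (ox + ix * vx - p0x) / ddx, vx / abs(ddx)
    else:
        step_x, t_nx, dtx = 0, inf, inf
    if ddy > 0.0:
        step_y, t_ny, dty = 1, (oy + (iy + 1) * vy - p0y) / ddy, vy / abs(ddy)
    elif ddy < 0.0:
        step_y, t_ny, dty = -1, (oy + iy * vy - p0y) / ddy, vy / abs(ddy)
    else:
        step_y, t_ny, dty = 0, inf, inf
    if ddz > 0.0:
        step_z, t_nz, dtz = 1, (oz + (iz + 1) * vz - p0z) / ddz, vz / abs(ddz)
    elif ddz < 0.0:
        step_z, t_nz, dtz = -1, (oz + iz * vz - p0z) / ddz, vz / abs(ddz)
    else:
        step_z, t_nz, dtz = 0, inf, inf

    n = 0
    while True:
        t_next = t_nx
        axis = 0
        if t_ny < t_next:
            t_next = t_ny
            axis = 1
        if t_nz < t_next:
            t_next = t_nz
            axis = 2
        if t_next > tmax:
            seg = (tmax - tcur) * length
            if seg > 0.0:
                out_idx[n] = (ix * ny + iy) * nz + iz
                out_len[n] = seg
                n += 1
            return n
        seg = (t_next - tcur) * length
        if seg > 0.0:
            out_idx[n] = (ix * ny + iy) * nz + iz
            out_len[n] = seg
            n += 1
        tcur = t_next
        if axis == 0:
            ix += step_x
            t_nx += dtx
            if ix < 0 or ix >= nx:
                return n
        elif axis == 1:
            iy += step_y
            t_ny += dty
            if iy < 0 or iy >= ny:
                return n
        else:
            iz += step_z
            t_nz += dtz
            if iz < 0 or iz >= nz:
                return n


@njit(cache=True)
def line_integrals(p0, p1, ox, oy, oz, vx, vy, vz, nx, ny, nz, values_flat):
    """Line integral of a voxel image along each segment p0[i] -> p1[i]."""
    n_rays = p0.shape[0]
    out = np.zeros(n_rays)
    cap = nx + ny + nz + 4
    idx = np.empty(cap, dtype=np.int64)
    seg = np.empty(cap)
    for i in range(n_rays):
        n = trace_ray(
            p0[i, 0], p0[i, 1], p0[i, 2], p1[i, 0], p1[i, 1], p1[i, 2],
            ox, oy, oz, vx, vy, vz, nx, ny, nz, idx, seg,
        )
        total = 0.0
        for k in range(n):
            total += values_flat[idx[k]] * seg[k]
        out[i] = total
    return out


@njit(cache=True)
def sensitivity_pass(
    detx, dety, detz, crystal_index, n_per_ring, min_sector,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    mu_flat, use_atten,
):
    """Sum of intersection lengths (x attenuation survival) over all
    admissible detector pairs -- the list-mode MLEM sensitivity image."""
    n_det = detx.shape[0]
    s = np.zeros(nx * ny * nz)
    cap = nx + ny + nz + 4
    idx = np.empty(cap, dtype=np.int64)
    seg = np.empty(cap)
    for a in range(n_det):
        ca = crystal_index[a]
        for b in range(a + 1, n_det):
            cb = crystal_index[b]
            diff = ca - cb
            if diff < 0:
                diff = -diff
            if n_per_ring - diff < diff:
                diff = n_per_ring - diff
            if diff < min_sector:
                continue
            n = trace_ray(
                detx[a], dety[a], detz[a], detx[b], dety[b], detz[b],
                ox, oy, oz, vx, vy, vz, nx, ny, nz, idx, seg,
            )
            if n <= 0:
                continue
            att = 1.0
            if use_atten:
                integ = 0.0
                for k in range(n):
                    integ += mu_flat[idx[k]] * seg[k]
                att = math.exp(-integ)
            for k in range(n):
                s[idx[k]] += seg[k] * att
    return s


@njit(cache=True)
def mlem_pass(
    pax, pay, paz, pbx, pby, pbz, dt_ps,
    sig_f, sig_s, alpha, tof_on, bin_w,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    lam_flat, trunc_nsigma,
):
    """One list-mode MLEM accumulation pass over all events.

    Returns ``(backprojection, sum_log_forward, n_skipped)``; the caller
    applies the multiplicative update with the sensitivity image.  TOF
    voxel weights are CDF differences of the event's mixture kernel over
    the TOF bin holding the measured time difference; weights farther than
    ``trunc_nsigma`` slow-component sigmas from the measured time are
    dropped (negligible kernel mass).
    """
    n_events = pax.shape[0]
    back = np.zeros(nx * ny * nz)
    cap = nx + ny + nz + 4
    idx = np.empty(cap, dtype=np.int64)
    seg = np.empty(cap)
    w = np.empty(cap)
    ll = 0.0
    skipped = 0
    for e in range(n_events):
        n = trace_ray(
            pax[e], pay[e], paz[e], pbx[e], pby[e], pbz[e],
            ox, oy, oz, vx, vy, vz, nx, ny, nz, idx, seg,
        )
        if n <= 0:
            skipped += 1
            continue
        q = 0.0
        if tof_on:
            dte = dt_ps[e]
            k1 = math.floor(dte / bin_w) * bin_w
            k2 = k1 + bin_w
            sf = sig_f[e]
            ss = sig_s[e]
            al = alpha[e]
            lcut = trunc_nsigma * ss
            # LOR midpoint and unit direction a -> b
            ux = pbx[e] - pax[e]
            uy = pby[e] - pay[e]
            uz = pbz[e] - paz[e]
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            mx = 0.5 * (pax[e] + pbx[e])
            my = 0.5 * (pay[e] + pby[e])
            mz = 0.5 * (paz[e] + pbz[e])
            for k in range(n):
                j = idx[k]
                iz = j % nz
                iy = (j // nz) % ny
                ix = j // (nz * ny)
                cx = ox + (ix + 0.5) * vx
                cy = oy + (iy + 0.5) * vy
                cz = oz + (iz + 0.5) * vz
                # signed axial position toward b, as a time (ps)
                spos = (cx - mx) * ux + (cy - my) * uy + (cz - mz) * uz
                v = 2.0 * spos / C_MM_PER_PS
                if abs(v - dte) > lcut:
                    w[k] = 0.0
                    continue
                kf = al * 0.5 * (
                    math.erf((k2 - v) / sf * _SQRT1_2) - math.erf((k1 - v) / sf * _SQRT1_2)
                ) + (1.0 - al) * 0.5 * (
                    math.erf((k2 - v) / ss * _SQRT1_2) - math.erf((k1 - v) / ss * _SQRT1_2)
                )
                wk = seg[k] * kf
                w[k] = wk
                q += wk * lam_flat[j]
        else:
            for k in range(n):
                w[k] = seg[k]
                q += seg[k] * lam_flat[idx[k]]
        if q <= 0.0:
            skipped += 1
            continue
        ll += math.log(q)
        for k in range(n):
            if w[k] > 0.0:
                back[idx[k]] += w[k] / q
    return back, ll, skipped
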