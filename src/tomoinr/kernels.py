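"""Numba kernels for the hot paths: hash encoding, B-spline interpolation
and divergent-beam projection.

Every forward kernel here has a matching backward kernel implementing the
exact vector-Jacobian product (for the projector, the exact adjoint), so
the pair can be wrapped as a custom op on the autodiff tape.  Accumulators
are float64 regardless of the working dtype to keep adjoint identities and
gradient checks tight.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# primes of the spatial hash (first one deliberately 1 so that the first
# coordinate passes through; the classic multiresolution-hash choice)
_P0, _P1, _P2 = np.uint64(1), np.uint64(2654435761), np.uint64(805459861)


# ---------------------------------------------------------------------------
# multiresolution hash encoding
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _hash_idx2(i0, i1, res, size, hashed):
    if hashed:
        h = (np.uint64(i0) * _P0) ^ (np.uint64(i1) * _P1)
        return np.int64(h % np.uint64(size))
    return np.int64(i0 + i1 * (res + 1))


@njit(cache=True, inline="always")
def _hash_idx3(i0, i1, i2, res, size, hashed):
    if hashed:
        h = (np.uint64(i0) * _P0) ^ (np.uint64(i1) * _P1) ^ (np.uint64(i2) * _P2)
        return np.int64(h % np.uint64(size))
    n = res + 1
    return np.int64(i0 + i1 * n + i2 * n * n)


@njit(cache=True, inline="always")
def _cell(c, res):
    """Clamp a coordinate to [-1, 1] and split into cell index + fraction."""
    cl = False
    if c < -1.0:
        c = -1.0
        cl = True
    elif c > 1.0:
        c = 1.0
        cl = True
    u = (c + 1.0) * 0.5 * res
    i0 = np.int64(np.floor(u))
    if i0 > res - 1:
        i0 = res - 1
    if i0 < 0:
        i0 = 0
    return i0, u - i0, cl


@njit(cache=True)
def hash_encode_fwd(coords, tables, level_res, level_off, level_hashed, n_feat):
    """coords (n, d) in [-1, 1] -> features (n, L * n_feat)."""
    n, d = coords.shape
    L = level_res.shape[0]
    out = np.zeros((n, L * n_feat), dtype=tables.dtype)
    for m in range(n):
        for lev in range(L):
            res = level_res[lev]
            off = level_off[lev]
            size = level_off[lev + 1] - off
            hashed = level_hashed[lev]
            col = lev * n_feat
            i0, f0, _ = _cell(coords[m, 0], res)
            if d == 1:
                ia = off + i0
                ib = off + i0 + 1
                for q in range(n_feat):
                    out[m, col + q] = (1.0 - f0) * tables[ia, q] + f0 * tables[ib, q]
            elif d == 2:
                i1, f1, _ = _cell(coords[m, 1], res)
                w00 = (1.0 - f0) * (1.0 - f1)
                w10 = f0 * (1.0 - f1)
                w01 = (1.0 - f0) * f1
                w11 = f0 * f1
                t00 = off + _hash_idx2(i0, i1, res, size, hashed)
                t10 = off + _hash_idx2(i0 + 1, i1, res, size, hashed)
                t01 = off + _hash_idx2(i0, i1 + 1, res, size, hashed)
                t11 = off + _hash_idx2(i0 + 1, i1 + 1, res, size, hashed)
                for q in range(n_feat):
                    out[m, col + q] = (
                        w00 * tables[t00, q] + w10 * tables[t10, q]
                        + w01 * tables[t01, q] + w11 * tables[t11, q]
                    )
            else:
                i1, f1, _ = _cell(coords[m, 1], res)
                i2, f2, _ = _cell(coords[m, 2], res)
                for c2 in range(2):
                    wz = f2 if c2 else 1.0 - f2
                    for c1 in range(2):
                        wy = wz * (f1 if c1 else 1.0 - f1)
                        for c0 in range(2):
                            w = wy * (f0 if c0 else 1.0 - f0)
                            t = off + _hash_idx3(i0 + c0, i1 + c1, i2 + c2, res, size, hashed)
                            for q in range(n_feat):
                                out[m, col + q] += w * tables[t, q]
    return out


@njit(cache=True)
def hash_encode_bwd(
    grad_out, coords, tables, level_res, level_off, level_hashed, n_feat,
    grad_tables, grad_coords, need_coord_grad,
):
    """Accumulate d(loss)/d(tables) and optionally d(loss)/d(coords)."""
    n, d = coords.shape
    L = level_res.shape[0]
    for m in range(n):
        for lev in range(L):
            res = level_res[lev]
            off = level_off[lev]
            size = level_off[lev + 1] - off
            hashed = level_hashed[lev]
            col = lev * n_feat
            half_res = 0.5 * res
            i0, f0, cl0 = _cell(coords[m, 0], res)
            if d == 1:
                ia = off + i0
                ib = off + i0 + 1
                for q in range(n_feat):
                    g = grad_out[m, col + q]
                    grad_tables[ia, q] += g * (1.0 - f0)
                    grad_tables[ib, q] += g * f0
                    if need_coord_grad and not cl0:
                        grad_coords[m, 0] += g * (tables[ib, q] - tables[ia, q]) * half_res
            elif d == 2:
                i1, f1, cl1 = _cell(coords[m, 1], res)
                t00 = off + _hash_idx2(i0, i1, res, size, hashed)
                t10 = off + _hash_idx2(i0 + 1, i1, res, size, hashed)
                t01 = off + _hash_idx2(i0, i1 + 1, res, size, hashed)
                t11 = off + _hash_idx2(i0 + 1, i1 + 1, res, size, hashed)
                for q in range(n_feat):
                    g = grad_out[m, col + q]
                    grad_tables[t00, q] += g * (1.0 - f0) * (1.0 - f1)
                    grad_tables[t10, q] += g * f0 * (1.0 - f1)
                    grad_tables[t01, q] += g * (1.0 - f0) * f1
                    grad_tables[t11, q] += g * f0 * f1
                    if need_coord_grad:
                        a00 = tables[t00, q]
                        a10 = tables[t10, q]
                        a01 = tables[t01, q]
                        a11 = tables[t11, q]
                        if not cl0:
                            grad_coords[m, 0] += (
                                g * ((a10 - a00) * (1.0 - f1) + (a11 - a01) * f1) * half_res
                            )
                        if not cl1:
                            grad_coords[m, 1] += (
                                g * ((a01 - a00) * (1.0 - f0) + (a11 - a10) * f0) * half_res
                            )
            else:
                i1, f1, cl1 = _cell(coords[m, 1], res)
                i2, f2, cl2 = _cell(coords[m, 2], res)
                for c2 in range(2):
                    w2 = f2 if c2 else 1.0 - f2
                    s2 = 1.0 if c2 else -1.0
                    for c1 in range(2):
                        w1 = f1 if c1 else 1.0 - f1
                        s1 = 1.0 if c1 else -1.0
                        for c0 in range(2):
                            w0 = f0 if c0 else 1.0 - f0
                            s0 = 1.0 if c0 else -1.0
                            t = off + _hash_idx3(i0 + c0, i1 + c1, i2 + c2, res, size, hashed)
                            for q in range(n_feat):
                                g = grad_out[m, col + q]
                                grad_tables[t, q] += g * w0 * w1 * w2
                                if need_coord_grad:
                                    a = tables[t, q]
                                    if not cl0:
                                        grad_coords[m, 0] += g * a * s0 * w1 * w2 * half_res
                                    if not cl1:
                                        grad_coords[m, 1] += g * a * w0 * s1 * w2 * half_res
                                    if not cl2:
                                        grad_coords[m, 2] += g * a * w0 * w1 * s2 * half_res


# ---------------------------------------------------------------------------
# tensor-product cubic B-spline interpolation (uniform knots)
# ---------------------------------------------------------------------------


@njit(cache=True)
def bspline_fwd(controls, base_idx, weights, strides):
    """controls (G, n_ctrl_flat); base_idx (n, d); weights (n, d, 4) -> (G, n)."""
    G = controls.shape[0]
    n, d = base_idx.shape
    out = np.zeros((G, n), dtype=controls.dtype)
    for g in range(G):
        for m in range(n):
            acc = 0.0
            if d == 1:
                for a in range(4):
                    acc += weights[m, 0, a] * controls[g, base_idx[m, 0] + a]
            elif d == 2:
                for a in range(4):
                    wa = weights[m, 0, a]
                    ia = (base_idx[m, 0] + a) * strides[0]
                    for bq in range(4):
                        acc += wa * weights[m, 1, bq] * controls[g, ia + base_idx[m, 1] + bq]
            else:
                for a in range(4):
                    wa = weights[m, 0, a]
                    ia = (base_idx[m, 0] + a) * strides[0]
                    for bq in range(4):
                        wb = wa * weights[m, 1, bq]
                        ib = ia + (base_idx[m, 1] + bq) * strides[1]
                        for cq in range(4):
                            acc += wb * weights[m, 2, cq] * controls[g, ib + base_idx[m, 2] + cq]
            out[g, m] = acc
    return out


@njit(cache=True)
def bspline_bwd(grad_out, base_idx, weights, strides, grad_controls):
    G = grad_controls.shape[0]
    n, d = base_idx.shape
    for g in range(G):
        for m in range(n):
            go = grad_out[g, m]
            if go == 0.0:
                continue
            if d == 1:
                for a in range(4):
                    grad_controls[g, base_idx[m, 0] + a] += go * weights[m, 0, a]
            elif d == 2:
                for a in range(4):
                    wa = go * weights[m, 0, a]
                    ia = (base_idx[m, 0] + a) * strides[0]
                    for bq in range(4):
                        grad_controls[g, ia + base_idx[m, 1] + bq] += wa * weights[m, 1, bq]
            else:
                for a in range(4):
                    wa = go * weights[m, 0, a]
                    ia = (base_idx[m, 0] + a) * strides[0]
                    for bq in range(4):
                        wb = wa * weights[m, 1, bq]
                        ib = ia + (base_idx[m, 1] + bq) * strides[1]
                        for cq in range(4):
                            grad_controls[g, ib + base_idx[m, 2] + cq] += wb * weights[m, 2, cq]


# ---------------------------------------------------------------------------
# ray-marching (Joseph-style) projector, 2-D and 3-D, with exact adjoints
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _ray_box(src, direction, lo, hi):
    """Entry/exit parameters of a ray against an axis-aligned box."""
    t0 = 0.0
    t1 = 1e30
    for j in range(src.shape[0]):
        dj = direction[j]
        if abs(dj) < 1e-12:
            if src[j] < lo[j] or src[j] > hi[j]:
                return 1.0, 0.0
        else:
            ta = (lo[j] - src[j]) / dj
            tb = (hi[j] - src[j]) / dj
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True)
def joseph_fwd_2d(vol, origin, spacing, lo, hi, src, pix, step):
    n_rays = pix.shape[0]
    nx, nz = vol.shape
    out = np.zeros(n_rays, dtype=vol.dtype)
    for r in range(n_rays):
        dx = pix[r, 0] - src[0]
        dz = pix[r, 1] - src[1]
        length = np.sqrt(dx * dx + dz * dz)
        dx /= length
        dz /= length
        direction = np.array((dx, dz))
        t0, t1 = _ray_box(src, direction, lo, hi)
        if t1 <= t0:
            continue
        nstep = int(np.ceil((t1 - t0) / step))
        dt = (t1 - t0) / nstep
        acc = 0.0
        for k in range(nstep):
            t = t0 + (k + 0.5) * dt
            px = (src[0] + t * dx - origin[0]) / spacing[0]
            pz = (src[1] + t * dz - origin[1]) / spacing[1]
            ix = np.int64(np.floor(px))
            iz = np.int64(np.floor(pz))
            fx = px - ix
            fz = pz - iz
            for a in range(2):
                wa = fx if a else 1.0 - fx
                xi = ix + a
                if xi < 0 or xi >= nx:
                    continue
                for b in range(2):
                    wb = fz if b else 1.0 - fz
                    zi = iz + b
                    if zi < 0 or zi >= nz:
                        continue
                    acc += wa * wb * vol[xi, zi]
        out[r] = acc * dt
    return out


@njit(cache=True)
def joseph_adj_2d(grad_rays, vol_shape, origin, spacing, lo, hi, src, pix, step, grad_vol):
    n_rays = pix.shape[0]
    nx, nz = vol_shape
    for r in range(n_rays):
        g = grad_rays[r]
        dx = pix[r, 0] - src[0]
        dz = pix[r, 1] - src[1]
        length = np.sqrt(dx * dx + dz * dz)
        dx /= length
        dz /= length
        direction = np.array((dx, dz))
        t0, t1 = _ray_box(src, direction, lo, hi)
        if t1 <= t0:
            continue
        nstep = int(np.ceil((t1 - t0) / step))
        dt = (t1 - t0) / nstep
        if g == 0.0:
            continue
        gdt = g * dt
        for k in range(nstep):
            t = t0 + (k + 0.5) * dt
            px = (src[0] + t * dx - origin[0]) / spacing[0]
            pz = (src[1] + t * dz - origin[1]) / spacing[1]
            ix = np.int64(np.floor(px))
            iz = np.int64(np.floor(pz))
            fx = px - ix
            fz = pz - iz
            for a in range(2):
                wa = fx if a else 1.0 - fx
                xi = ix + a
                if xi < 0 or xi >= nx:
                    continue
                for b in range(2):
                    wb = fz if b else 1.0 - fz
                    zi = iz + b
                    if zi < 0 or zi >= nz:
                        continue
                    grad_vol[xi, zi] += gdt * wa * wb
    return grad_vol


@njit(cache=True)
def joseph_fwd_3d(vol, origin, spacing, lo, hi, src, pix, step):
    n_rays = pix.shape[0]
    nx, ny, nz = vol.shape
    out = np.zeros(n_rays, dtype=vol.dtype)
    for r in range(n_rays):
        d0 = pix[r, 0] - src[0]
        d1 = pix[r, 1] - src[1]
        d2 = pix[r, 2] - src[2]
        length = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        d0 /= length
        d1 /= length
        d2 /= length
        direction = np.array((d0, d1, d2))
        t0, t1 = _ray_box(src, direction, lo, hi)
        if t1 <= t0:
            continue
        nstep = int(np.ceil((t1 - t0) / step))
        dt = (t1 - t0) / nstep
        acc = 0.0
        for k in range(nstep):
            t = t0 + (k + 0.5) * dt
            p0 = (src[0] + t * d0 - origin[0]) / spacing[0]
            p1 = (src[1] + t * d1 - origin[1]) / spacing[1]
            p2 = (src[2] + t * d2 - origin[2]) / spacing[2]
            i0 = np.int64(np.floor(p0))
            i1 = np.int64(np.floor(p1))
            i2 = np.int64(np.floor(p2))
            f0 = p0 - i0
            f1 = p1 - i1
            f2 = p2 - i2
            for a in range(2):
                wa = f0 if a else 1.0 - f0
                xi = i0 + a
                if xi < 0 or xi >= nx:
                    continue
                for b in range(2):
                    wb = wa * (f1 if b else 1.0 - f1)
                    yi = i1 + b
                    if yi < 0 or yi >= ny:
                        continue
                    for c in range(2):
                        wc = wb * (f2 if c else 1.0 - f2)
                        zi = i2 + c
                        if zi < 0 or zi >= nz:
                            continue
                        acc += wc * vol[xi, yi, zi]
        out[r] = acc * dt
    return out


@njit(cache=True)
def joseph_adj_3d(grad_rays, vol_shape, origin, spacing, lo, hi, src, pix, step, grad_vol):
    n_rays = pix.shape[0]
    nx, ny, nz = vol_shape
    for r in range(n_rays):
        g = grad_rays[r]
        d0 = pix[r, 0] - src[0]
        d1 = pix[r, 1] - src[1]
        d2 = pix[r, 2] - src[2]
        length = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        d0 /= length
        d1 /= length
        d2 /= length
        direction = np.array((d0, d1, d2))
        t0, t1 = _ray_box(src, direction, lo, hi)
        if t1 <= t0:
            continue
        nstep = int(np.ceil((t1 - t0) / step))
        dt = (t1 - t0) / nstep
        if g == 0.0:
            continue
        gdt = g * dt
        for k in range(nstep):
            t = t0 + (k + 0.5) * dt
            p0 = (src[0] + t * d0 - origin[0]) / spacing[0]
            p1 = (src[1] + t * d1 - origin[1]) / spacing[1]
            p2 = (src[2] + t * d2 - origin[2]) / spacing[2]
            i0 = np.int64(np.floor(p0))
            i1 = np.int64(np.floor(p1))
            i2 = np.int64(np.floor(p2))
            f0 = p0 - i0
            f1 = p1 - i1
            f2 = p2 - i2
            for a in range(2):
                wa = f0 if a else 1.0 - f0
                xi = i0 + a
                if xi < 0 or xi >= nx:
                    continue
                for b in range(2):
                    wb = wa * (f1 if b else 1.0 - f1)
                    yi = i1 + b
                    if yi < 0 or yi >= ny:
                        continue
                    for c in range(2):
                        wc = wb * (f2 if c else 1.0 - f2)
                        zi = i2 + c
                        if zi < 0 or zi >= nz:
                            continue
                        grad_vol[xi, yi, zi] += gdt * wc
    return grad_vol


# ---------------------------------------------------------------------------
# Siddon projector (exact ray-voxel intersection lengths)
# ---------------------------------------------------------------------------


@njit(cache=True)
def siddon_2d(vol_or_none, vol_shape, origin, spacing, src, pix, adjoint, grad_rays, grad_vol):
    """Exact intersection-length projector (2-D).

    Forward mode (``adjoint == 0``): returns line integrals over ``vol_or_none``.
    Adjoint mode: scatters ``grad_rays`` weighted by the same lengths into
    ``grad_vol``.
    """
    n_rays = pix.shape[0]
    nx, nz = vol_shape
    lo0 = origin[0] - 0.5 * spacing[0]
    lo1 = origin[1] - 0.5 * spacing[1]
    hi0 = lo0 + nx * spacing[0]
    hi1 = lo1 + nz * spacing[1]
    lo = np.array((lo0, lo1))
    hi = np.array((hi0, hi1))
    out = np.zeros(n_rays, dtype=np.float64)
    for r in range(n_rays):
        dx = pix[r, 0] - src[0]
        dz = pix[r, 1] - src[1]
        length = np.sqrt(dx * dx + dz * dz)
        dx /= length
        dz /= length
        direction = np.array((dx, dz))
        t0, t1 = _ray_box(src, direction, lo, hi)
        if t1 <= t0 + 1e-12:
            continue
        t = t0
        acc = 0.0
        g = grad_rays[r] if adjoint else 0.0
        while t < t1 - 1e-10:
            # voxel containing the point just after t
            eps = 1e-9 * (t1 - t0)
            px = src[0] + (t + eps) * dx
            pz = src[1] + (t + eps) * dz
            ix = np.int64(np.floor((px - lo0) / spacing[0]))
            iz = np.int64(np.floor((pz - lo1) / spacing[1]))
            if ix < 0 or ix >= nx or iz < 0 or iz >= nz:
                break
            # parameter of exit from this voxel
            t_next = t1
            if abs(dx) > 1e-12:
                edge = lo0 + (ix + (1 if dx > 0 else 0)) * spacing[0]
                tn = (edge - src[0]) / dx
                if tn < t_next:
                    t_next = tn
            if abs(dz) > 1e-12:
                edge = lo1 + (iz + (1 if dz > 0 else 0)) * spacing[1]
                tn = (edge - src[1]) / dz
                if tn < t_next:
                    t_next = tn
            if t_next <= t:
                t_next = t + 1e-9 * (t1 - t0)
            seg = min(t_next, t1) - t
            if adjoint:
                grad_vol[ix, iz] += g * seg
            else:
                acc += vol_or_none[ix, iz] * seg
            t = t_next
        out[r] = acc
    return out


@njit(cache=True)
def siddon_3d(vol_or_none, vol_shape, origin, spacing, src, pix, adjoint, grad_rays, grad_vol):
    n_rays = pix.shape[0]
    nx, ny, nz = vol_shape
    lo = np.array(
        (origin[0] - 0.5 * spacing[0], origin[1] - 0.5 * spacing[1], origin[2] - 0.5 * spacing[2])
    )
    hi = np.array((lo[0] + nx * spacing[0], lo[1] + ny * spacing[1], lo[2] + nz * spacing[2]))
    out = np.zeros(n_rays, dtype=np.float64)
    for r in range(n_rays):
        d = np.array((pix[r, 0] - src[0], pix[r, 1] - src[1], pix[r, 2] - src[2]))
        length = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        d /= length
        t0, t1 = _ray_box(src, d, lo, hi)
        if t1 <= t0 + 1e-12:
            continue
        t = t0
        acc = 0.0
        g = grad_rays[r] if adjoint else 0.0
        while t < t1 - 1e-10:
            eps = 1e-9 * (t1 - t0)
            i = np.empty(3, dtype=np.int64)
            ok = True
            for j in range(3):
                p = src[j] + (t + eps) * d[j]
                i[j] = np.int64(np.floor((p - lo[j]) / spacing[j]))
                if i[j] < 0 or (j == 0 and i[j] >= nx) or (j == 1 and i[j] >= ny) or (j == 2 and i[j] >= nz):
                    ok = False
            if not ok:
                break
            t_next = t1
            for j in range(3):
                if abs(d[j]) > 1e-12:
                    edge = lo[j] + (i[j] + (1 if d[j] > 0 else 0)) * spacing[j]
                    tn = (edge - src[j]) / d[j]
                    if tn < t_next:
                        t_next = tn
            if t_next <= t:
                t_next = t + 1e-9 * (t1 - t0)
            seg = min(t_next, t1) - t
            if adjoint:
                grad_vol[i[0], i[1], i[2]] += g * seg
            else:
                acc += vol_or_none[i[0], i[1], i[2]] * seg
            t = t_next
        out[r] = acc
    return out
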