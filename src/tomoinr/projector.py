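"""Divergent-beam forward/adjoint projection and FDK/FBP reconstruction.

The forward operator is a Joseph-style ray marcher (linear interpolation,
fixed step <= half the minimum voxel spacing) whose adjoint scatters the
identical interpolation weights, so ``<P x, y> == <x, P^T y>`` holds to
rounding.  A Siddon mode computes exact ray-voxel intersection lengths and
serves as the geometric reference operator.  Both support the 3-D cone-beam
and the 2-D flatland fan-beam geometries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .autodiff import Tensor, custom
from .geometry import ProjectionSet, ScanGeometry, Volume, VolumeGrid

__all__ = [
    "ProjectorConfig",
    "source_position",
    "pixel_positions",
    "forward_project",
    "back_project",
    "forward_project_batch_op",
    "fdk_reconstruct",
]


@dataclass
class ProjectorConfig:
    method: str = "joseph"  # {"joseph", "siddon"}
    step_fraction: float = 0.5  # Joseph step as a fraction of min voxel spacing

    def __post_init__(self):
        if self.method not in ("joseph", "siddon"):
            raise ValueError(f"unknown projector method {self.method!r}")
        if not 0 < self.step_fraction <= 0.5:
            raise ValueError("step_fraction must be in (0, 0.5]")


def _rot(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def source_position(geom: ScanGeometry, angle_deg: float) -> np.ndarray:
    """World position of the x-ray source at a gantry angle."""
    xy = _rot(angle_deg) @ np.array([0.0, geom.sad])
    if geom.ndim == 2:
        return xy  # flatland axes: (in-plane 1, in-plane 2)
    return np.array([xy[0], xy[1], 0.0])


def pixel_positions(geom: ScanGeometry, angle_deg: float) -> np.ndarray:
    """World positions of all detector pixel centers; shape (n_rays, ndim).

    3-D rays are ordered row-major over (v, u) to match frame layout.
    """
    R = _rot(angle_deg)
    center = R @ np.array([0.0, geom.sad - geom.sdd])
    u_vec = R @ np.array([1.0, 0.0])
    u = geom.u_coords()
    if geom.ndim == 2:
        return center[None, :] + u[:, None] * u_vec[None, :]
    v = geom.v_coords()
    uu, vv = np.meshgrid(u, v)  # (n_v, n_u)
    pts = np.empty((geom.n_v * geom.n_u, 3))
    pts[:, 0] = center[0] + uu.ravel() * u_vec[0]
    pts[:, 1] = center[1] + uu.ravel() * u_vec[1]
    pts[:, 2] = vv.ravel()
    return pts


def _check_source_outside(grid: VolumeGrid, src: np.ndarray):
    lo, hi = grid.bounds()
    if np.all(src >= lo) and np.all(src <= hi):
        raise ValueError("degenerate geometry: source inside the volume")


def _frame_geometry(grid: VolumeGrid, geom: ScanGeometry, angle_deg: float):
    src = source_position(geom, angle_deg)
    _check_source_outside(grid, src)
    pix = pixel_positions(geom, angle_deg)
    lo, hi = grid.bounds()
    return (
        src.astype(np.float64),
        pix.astype(np.float64),
        lo.astype(np.float64),
        hi.astype(np.float64),
        np.asarray(grid.origin, dtype=np.float64),
        np.asarray(grid.spacing, dtype=np.float64),
    )


def _resolve_angle(geom: ScanGeometry, frame) -> float:
    """Frame index (int) or explicit angle in degrees (float)."""
    if isinstance(frame, (int, np.integer)):
        return float(geom.angles[frame])
    return float(frame)


def forward_project(
    vol: Volume, geom: ScanGeometry, frame, config: ProjectorConfig | None = None
) -> np.ndarray:
    """Line integrals of ``vol`` along every source-pixel ray of one frame."""
    config = config or ProjectorConfig()
    angle = _resolve_angle(geom, frame)
    src, pix, lo, hi, origin, spacing = _frame_geometry(vol.grid, geom, angle)
    step = config.step_fraction * min(vol.grid.spacing)
    values = np.ascontiguousarray(vol.values)
    if config.method == "joseph":
        if vol.grid.ndim == 2:
            out = kernels.joseph_fwd_2d(values, origin, spacing, lo, hi, src, pix, step)
        else:
            out = kernels.joseph_fwd_3d(values, origin, spacing, lo, hi, src, pix, step)
    else:
        dummy = np.zeros(pix.shape[0])
        gvol = np.zeros(vol.grid.shape)
        fn = kernels.siddon_2d if vol.grid.ndim == 2 else kernels.siddon_3d
        out = fn(
            values.astype(np.float64), np.array(vol.grid.shape, dtype=np.int64),
            origin, spacing, src, pix, 0, dummy, gvol,
        ).astype(values.dtype)
    return out.reshape(geom.frame_shape)


def back_project(
    frame_values: np.ndarray,
    grid: VolumeGrid,
    geom: ScanGeometry,
    frame,
    config: ProjectorConfig | None = None,
) -> Volume:
    """Exact adjoint of :func:`forward_project` for one frame."""
    config = config or ProjectorConfig()
    frame_values = np.asarray(frame_values)
    if frame_values.shape != geom.frame_shape:
        raise ValueError(f"frame shape {frame_values.shape} != {geom.frame_shape}")
    angle = _resolve_angle(geom, frame)
    src, pix, lo, hi, origin, spacing = _frame_geometry(grid, geom, angle)
    step = config.step_fraction * min(grid.spacing)
    g = np.ascontiguousarray(frame_values.ravel())
    out = np.zeros(grid.shape, dtype=frame_values.dtype)
    if config.method == "joseph":
        shape = np.array(grid.shape, dtype=np.int64)
        if grid.ndim == 2:
            kernels.joseph_adj_2d(g, shape, origin, spacing, lo, hi, src, pix, step, out)
        else:
            kernels.joseph_adj_3d(g, shape, origin, spacing, lo, hi, src, pix, step, out)
    else:
        out64 = np.zeros(grid.shape, dtype=np.float64)
        fn = kernels.siddon_2d if grid.ndim == 2 else kernels.siddon_3d
        fn(
            out64, np.array(grid.shape, dtype=np.int64), origin, spacing, src, pix,
            1, g.astype(np.float64), out64,
        )
        out = out64.astype(frame_values.dtype)
    return Volume(grid, out)


def forward_project_batch_op(
    volumes: Tensor,
    grid: VolumeGrid,
    geom: ScanGeometry,
    frame_indices: np.ndarray,
    config: ProjectorConfig | None = None,
) -> Tensor:
    """Differentiable projection of a batch of volumes at per-frame angles.

    ``volumes`` has shape (B, *grid.shape); frame ``b`` is projected at
    ``geom.angles[frame_indices[b]]``.  Output shape (B, n_rays).
    """
    config = config or ProjectorConfig()
    if config.method != "joseph":
        raise ValueError("the differentiable batch projector uses the joseph method")
    step = config.step_fraction * min(grid.spacing)
    shape = np.array(grid.shape, dtype=np.int64)
    geoms = [_frame_geometry(grid, geom, float(geom.angles[t])) for t in frame_indices]
    fwd_k = kernels.joseph_fwd_2d if grid.ndim == 2 else kernels.joseph_fwd_3d
    adj_k = kernels.joseph_adj_2d if grid.ndim == 2 else kernels.joseph_adj_3d

    def forward(vols):
        B = vols.shape[0]
        n_rays = geoms[0][1].shape[0]
        out = np.empty((B, n_rays), dtype=vols.dtype)
        for b in range(B):
            src, pix, lo, hi, origin, spacing = geoms[b]
            out[b] = fwd_k(np.ascontiguousarray(vols[b]), origin, spacing, lo, hi, src, pix, step)
        return out

    def vjp(g, out, vols):
        gv = np.zeros_like(vols)
        for b in range(vols.shape[0]):
            src, pix, lo, hi, origin, spacing = geoms[b]
            adj_k(np.ascontiguousarray(g[b]), shape, origin, spacing, lo, hi, src, pix, step, gv[b])
        return (gv,)

    return custom(forward, vjp, volumes)


def project_single_volume_op(
    volume: Tensor,
    grid: VolumeGrid,
    geom: ScanGeometry,
    frame_indices: np.ndarray,
    config: ProjectorConfig | None = None,
) -> Tensor:
    """Differentiable projection of one volume at several frame angles.

    ``volume`` has shape ``grid.shape``; output (len(frame_indices), n_rays).
    The adjoint accumulates every frame's backprojection into the volume.
    """
    config = config or ProjectorConfig()
    if config.method != "joseph":
        raise ValueError("the differentiable projector uses the joseph method")
    step = config.step_fraction * min(grid.spacing)
    shape = np.array(grid.shape, dtype=np.int64)
    geoms = [_frame_geometry(grid, geom, float(geom.angles[t])) for t in frame_indices]
    fwd_k = kernels.joseph_fwd_2d if grid.ndim == 2 else kernels.joseph_fwd_3d
    adj_k = kernels.joseph_adj_2d if grid.ndim == 2 else kernels.joseph_adj_3d

    def forward(vol):
        v = np.ascontiguousarray(vol)
        out = np.empty((len(geoms), geoms[0][1].shape[0]), dtype=vol.dtype)
        for b, (src, pix, lo, hi, origin, spacing) in enumerate(geoms):
            out[b] = fwd_k(v, origin, spacing, lo, hi, src, pix, step)
        return out

    def vjp(g, out, vol):
        gv = np.zeros_like(vol)
        for b, (src, pix, lo, hi, origin, spacing) in enumerate(geoms):
            adj_k(np.ascontiguousarray(g[b]), shape, origin, spacing, lo, hi, src, pix, step, gv)
        return (gv,)

    return custom(forward, vjp, volume)


# ---------------------------------------------------------------------------
# FDK / fan-beam FBP
# ---------------------------------------------------------------------------


def _ramlak_kernel(n: int, d: float) -> np.ndarray:
    """Spatial-domain Ram-Lak kernel for sample spacing ``d``."""
    k = np.arange(-n + 1, n)
    h = np.zeros_like(k, dtype=np.float64)
    h[k == 0] = 1.0 / (4.0 * d * d)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * d) ** 2
    return h


def _ramp_filter_rows(rows: np.ndarray, d: float) -> np.ndarray:
    """Ram-Lak filter each row (last axis), FFT convolution with zero padding."""
    n = rows.shape[-1]
    h = _ramlak_kernel(n, d)
    size = 1
    while size < n + h.size - 1:
        size *= 2
    H = np.fft.rfft(h, size)
    R = np.fft.rfft(rows, size, axis=-1)
    full = np.fft.irfft(R * H, size, axis=-1)
    return full[..., n - 1 : 2 * n - 1] * d


def _angular_weights(angles_deg: np.ndarray) -> np.ndarray:
    """Per-frame angular spans (rad); non-uniform spacing supported."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    if a.size < 2:
        raise ValueError("FDK needs at least 2 frames")
    d = np.gradient(a)
    return np.abs(d)


def fdk_reconstruct(pset: ProjectionSet, out_grid: VolumeGrid) -> Volume:
    """Feldkamp-Davis-Kress reconstruction (fan-beam FBP in flatland).

    Cosine weighting, Ram-Lak ramp filtering along u, and distance-weighted
    backprojection.  Half-fan sets are handled by plain FDK with the offset
    detector (no redundancy weighting), which is adequate for use as a
    motion-averaged initializer.
    """
    geom = pset.geometry
    if pset.n_frames < 2:
        raise ValueError("FDK needs at least 2 frames")
    sad, sdd = geom.sad, geom.sdd
    mag = sad / sdd
    u_iso = geom.u_coords() * mag  # detector coords rescaled to the iso plane
    du_iso = geom.du * mag
    weights_t = _angular_weights(geom.angles)

    if geom.ndim == 2:
        cosw = sad / np.sqrt(sad**2 + u_iso**2)
        filtered = np.empty_like(pset.frames, dtype=np.float64)
        for t in range(pset.n_frames):
            filtered[t] = _ramp_filter_rows(pset.frames[t] * cosw, du_iso)
        xs = out_grid.axis_coords(0)
        zs = out_grid.axis_coords(1)
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        out = np.zeros(out_grid.shape, dtype=np.float64)
        for t in range(pset.n_frames):
            a = np.deg2rad(geom.angles[t])
            c, s = np.cos(a), np.sin(a)
            # coordinates in the rotated frame where the source sits at (0, sad)
            xr = c * X + s * Z
            yr = -s * X + c * Z
            L = sad - yr
            u_p = xr * sad / L
            idx = (u_p - u_iso[0]) / du_iso
            i0 = np.floor(idx).astype(np.int64)
            f = idx - i0
            i0c = np.clip(i0, 0, geom.n_u - 1)
            i1c = np.clip(i0 + 1, 0, geom.n_u - 1)
            valid = (idx >= 0) & (idx <= geom.n_u - 1)
            q = filtered[t][i0c] * (1 - f) + filtered[t][i1c] * f
            out += weights_t[t] * np.where(valid, q, 0.0) * (sad**2 / L**2)
        out *= 0.5  # full-turn redundancy
        return Volume(out_grid, out)

    # 3-D cone beam
    v_iso = geom.v_coords() * mag
    dv_iso = geom.dv * mag
    UU, VV = np.meshgrid(u_iso, v_iso)
    cosw = sad / np.sqrt(sad**2 + UU**2 + VV**2)
    filtered = np.empty_like(pset.frames, dtype=np.float64)
    for t in range(pset.n_frames):
        filtered[t] = _ramp_filter_rows(pset.frames[t] * cosw, du_iso)
    xs = out_grid.axis_coords(0)
    ys = out_grid.axis_coords(1)
    zs = out_grid.axis_coords(2)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    out = np.zeros(out_grid.shape, dtype=np.float64)
    for t in range(pset.n_frames):
        a = np.deg2rad(geom.angles[t])
        c, s = np.cos(a), np.sin(a)
        xr = c * X + s * Y
        yr = -s * X + c * Y
        L = sad - yr  # (nx, ny)
        u_p = xr * sad / L
        iu = (u_p - u_iso[0]) / du_iso
        iu0 = np.floor(iu).astype(np.int64)
        fu = iu - iu0
        iu0c = np.clip(iu0, 0, geom.n_u - 1)
        iu1c = np.clip(iu0 + 1, 0, geom.n_u - 1)
        valid_u = (iu >= 0) & (iu <= geom.n_u - 1)
        w_t = weights_t[t] * sad**2 / L**2
        for kz, z in enumerate(zs):
            v_p = z * sad / L
            iv = (v_p - v_iso[0]) / dv_iso
            iv0 = np.floor(iv).astype(np.int64)
            fv = iv - iv0
            iv0c = np.clip(iv0, 0, geom.n_v - 1)
            iv1c = np.clip(iv0 + 1, 0, geom.n_v - 1)
            valid = valid_u & (iv >= 0) & (iv <= geom.n_v - 1)
            ft = filtered[t]
            q = (
                ft[iv0c, iu0c] * (1 - fu) * (1 - fv)
                + ft[iv0c, iu1c] * fu * (1 - fv)
                + ft[iv1c, iu0c] * (1 - fu) * fv
                + ft[iv1c, iu1c] * fu * fv
            )
            out[:, :, kz] += np.where(valid, q, 0.0) * w_t
    out *= 0.5
    return Volume(out_grid, out)
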