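"""Cubic B-spline motion basis components (MBCs) and DVF composition.

The deformation field is factorized as ``d_k(x, t) = sum_i w_{i,k}(t) *
e_{i,k}(x)``: per Cartesian direction ``k`` there are ``L`` spatial basis
fields, each a tensor-product cubic B-spline over a uniform control grid of
its own resolution (coarse -> fine across basis levels).  The spline domain
is the normalized [0, 1]^d cube over the reconstruction field of view, and
control values are displacements in the same normalized units (a fraction
of the box extent per axis), converted to mm only at the interface.  The
normalized convention keeps the temporal weights O(1) under the voxel-sum
orthonormality constraint on the basis fields; with mm-valued controls the
weights would have to reach O(10^2-10^3), which the published learning
rates cannot deliver.

Knots are uniform with the valid span covering exactly [0, 1]; queries
outside the span clamp (warped coordinates may exit the box slightly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .autodiff import Tensor
from .geometry import VolumeGrid

__all__ = [
    "cox_de_boor_basis",
    "uniform_knots",
    "bspline_weights",
    "BSplineGrid",
    "MotionBasisSet",
    "eval_mbc",
    "compose_dvf",
    "warp_reference",
    "mbc_orthonormality_loss",
]


def cox_de_boor_basis(x: float, l: int, p: int, knots: np.ndarray) -> float:
    """B-spline basis B_{l,p}(x) by the Cox-de Boor recursion.

    Degree 0 is the half-open indicator on [s_l, s_{l+1}); 0/0 terms in the
    recursion are defined as 0.
    """
    if p < 0:
        raise ValueError("order must be >= 0")
    knots = np.asarray(knots, dtype=np.float64)
    if np.any(np.diff(knots) < 0):
        raise ValueError("knots must be non-decreasing")
    if p == 0:
        return 1.0 if knots[l] <= x < knots[l + 1] else 0.0
    left_den = knots[l + p] - knots[l]
    right_den = knots[l + p + 1] - knots[l + 1]
    left = 0.0 if left_den == 0 else (x - knots[l]) / left_den * cox_de_boor_basis(x, l, p - 1, knots)
    right = (
        0.0
        if right_den == 0
        else (knots[l + p + 1] - x) / right_den * cox_de_boor_basis(x, l + 1, p - 1, knots)
    )
    return left + right


def uniform_knots(n_controls: int) -> np.ndarray:
    """Uniform cubic knot vector whose valid span is exactly [0, 1].

    ``n_controls`` >= 4; knots run from -3h to 1+3h with h = 1/(n_controls-3).
    """
    if n_controls < 4:
        raise ValueError("cubic B-splines need at least 4 controls per axis")
    h = 1.0 / (n_controls - 3)
    return (np.arange(n_controls + 4) - 3) * h


def bspline_weights(coords01: np.ndarray, n_controls: np.ndarray):
    """Per-point cell indices and the 4 cubic basis weights per axis.

    ``coords01`` (n, d) in [0, 1] (clamped); ``n_controls`` (d,).  Returns
    ``base_idx`` (n, d) int64 and ``weights`` (n, d, 4) such that the
    interpolant is ``sum over 4^d corners of prod(weights) * P[base+offset]``.
    """
    coords01 = np.atleast_2d(np.asarray(coords01, dtype=np.float64))
    n, d = coords01.shape
    n_controls = np.asarray(n_controls, dtype=np.int64)
    base_idx = np.empty((n, d), dtype=np.int64)
    weights = np.empty((n, d, 4), dtype=np.float64)
    for j in range(d):
        N = int(n_controls[j])
        t = np.clip(coords01[:, j], 0.0, 1.0) * (N - 3)
        cell = np.minimum(np.floor(t).astype(np.int64), N - 4)
        u = t - cell
        base_idx[:, j] = cell
        weights[:, j, 0] = (1 - u) ** 3 / 6.0
        weights[:, j, 1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
        weights[:, j, 2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
        weights[:, j, 3] = u**3 / 6.0
    return base_idx, weights


@dataclass
class BSplineGrid:
    """One resolution level of the motion model: control grids for every
    Cartesian direction, plus the shared uniform knots."""

    level: int
    control_shape: tuple[int, ...]
    controls: Tensor  # (n_dirs, *control_shape), normalized-box displacements

    @property
    def n_dirs(self) -> int:
        return self.controls.data.shape[0]

    def knots(self, axis: int = 0) -> np.ndarray:
        return uniform_knots(self.control_shape[axis])


class MotionBasisSet:
    """L multiresolution B-spline basis fields per Cartesian direction."""

    def __init__(self, ndim: int, controls_per_axis=(6, 12, 24), dtype=np.float64):
        self.ndim = int(ndim)
        self.levels: list[BSplineGrid] = []
        for i, n in enumerate(controls_per_axis):
            shape = (int(n),) * self.ndim
            controls = Tensor(
                np.zeros((self.ndim,) + shape, dtype=dtype), requires_grad=True
            )
            self.levels.append(BSplineGrid(level=i, control_shape=shape, controls=controls))
        self._basis_cache: dict = {}

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def parameters(self) -> dict[str, Tensor]:
        return {f"mbc.level{g.level}": g.controls for g in self.levels}

    def basis_for(self, coords01: np.ndarray, level: int, cache_key=None):
        """(Cached) interpolation stencil of a level at a fixed set of points."""
        key = (cache_key, level)
        if cache_key is not None and key in self._basis_cache:
            return self._basis_cache[key]
        n_ctrl = np.array(self.levels[level].control_shape, dtype=np.int64)
        base_idx, weights = bspline_weights(coords01, n_ctrl)
        strides = np.array(
            [int(np.prod(n_ctrl[j + 1 :])) for j in range(self.ndim)], dtype=np.int64
        )
        out = (base_idx, weights, strides)
        if cache_key is not None:
            self._basis_cache[key] = out
        return out

    def eval_level(self, level: int, coords01: np.ndarray, cache_key=None) -> Tensor:
        """Differentiable e_{i,k} values of one level at given points.

        Returns a Tensor (n_dirs, n_points), linear in the control values.
        """
        base_idx, weights, strides = self.basis_for(coords01, level, cache_key)
        grid = self.levels[level]
        controls = grid.controls
        flat_shape = (self.ndim, int(np.prod(grid.control_shape)))

        def vjp(g):
            gc = np.zeros(flat_shape, dtype=controls.data.dtype)
            kernels.bspline_bwd(np.ascontiguousarray(g), base_idx, weights, strides, gc)
            return (gc.reshape(controls.data.shape),)

        out = kernels.bspline_fwd(
            controls.data.reshape(flat_shape), base_idx, weights, strides
        )
        return Tensor._from_op(out, (controls,), vjp)

    def eval_level_numpy(self, level: int, coords01: np.ndarray) -> np.ndarray:
        base_idx, weights, strides = self.basis_for(coords01, level)
        grid = self.levels[level]
        flat = grid.controls.data.reshape(self.ndim, -1)
        return kernels.bspline_fwd(flat, base_idx, weights, strides)


def eval_mbc(mbcs: MotionBasisSet, coords01: np.ndarray) -> np.ndarray:
    """All basis fields at normalized points: array (L, n_dirs, n_points), mm."""
    return np.stack(
        [mbcs.eval_level_numpy(i, coords01) for i in range(mbcs.n_levels)], axis=0
    )


def compose_dvf(
    weights: np.ndarray, mbc_values: np.ndarray, box_extent: np.ndarray | None = None
) -> np.ndarray:
    """d_k(x, t) = sum_i w_{i,k}(t) e_{i,k}(x).

    ``weights``: (L * n_dirs,) ordered (i, k); ``mbc_values``: (L, n_dirs, n)
    from :func:`eval_mbc`.  Returns (n, n_dirs) displacements, bilinear in
    (weights, control values) -- in normalized box units, or in mm when the
    per-axis ``box_extent`` (mm) is given.
    """
    L, K, n = mbc_values.shape
    w = np.asarray(weights, dtype=np.float64).reshape(-1)
    if w.size != L * K:
        raise ValueError(f"expected {L * K} weights, got {w.size}")
    w = w.reshape(L, K)
    d = np.einsum("ik,ikn->nk", w, mbc_values)
    if box_extent is not None:
        d = d * np.asarray(box_extent, dtype=np.float64)[None, :]
    return d


def grid_coords01(grid: VolumeGrid, fov_grid: VolumeGrid) -> np.ndarray:
    """Voxel centers of ``grid`` in the [0,1]^d spline domain of ``fov_grid``."""
    lo, hi = fov_grid.bounds()
    pts = grid.voxel_centers()
    return (pts - lo) / (hi - lo)


def warp_reference(spatial_inr, dvf: np.ndarray, out_grid: VolumeGrid):
    """Pull-style warp: I(x, t) = I_ref(x + d(x, t)) via continuous INR queries.

    ``dvf`` gives displacements (mm) at the voxel centers of ``out_grid``,
    shape (*out_grid.shape, ndim) or (n_voxels, ndim).  With a zero field the
    output is exactly the gridded reference rendering.
    """
    from .geometry import Volume

    d = np.asarray(dvf, dtype=np.float64).reshape(out_grid.n_voxels, out_grid.ndim)
    coords = out_grid.voxel_centers() + d
    values = spatial_inr.eval_world(coords).reshape(out_grid.shape)
    return Volume(out_grid, values)


def mbc_orthonormality_loss(mbc_grid_values: Tensor, norm_scale: float = 1.0) -> Tensor:
    """Orthonormality regularizer over the basis fields, gridded on image voxels.

    ``mbc_grid_values`` is a Tensor (L, n_dirs, n_voxels) -- one row per basis
    level, evaluated at every image voxel.  Per direction k:

        sum_i | ||e_{i,k}||^2 * norm_scale - 1 |^2 + sum_{j>i} | e_{i,k} . e_{j,k} |^2

    with plain voxel-sum inner products, averaged over the L*n_dirs fields.
    ``norm_scale`` compensates the voxel-count change between resolution
    scales (1 at the low scale, 1/2^d after the 2x upsampling).
    """
    L, K, _ = mbc_grid_values.shape
    total = None
    for k in range(K):
        rows = [mbc_grid_values[i, k] for i in range(L)]
        for i in range(L):
            norm_term = ((rows[i] * rows[i]).sum() * norm_scale + (-1.0)).square()
            total = norm_term if total is None else total + norm_term
            for j in range(i + 1, L):
                total = total + ((rows[i] * rows[j]).sum()).square()
    return total * (1.0 / (L * K))
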