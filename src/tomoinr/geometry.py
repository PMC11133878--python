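"""Scan-geometry and image-container types.

Conventions (fixed for the whole package):

* world coordinates in mm, voxel-center convention, 0-based indices;
* axes ``x`` = left-right, ``y`` = anterior-posterior, ``z`` =
  superior-inferior;
* gantry angle 0 deg puts the source on the +y axis; rotation is
  counter-clockwise about the z axis viewed from +z;
* ``ndim == 2`` is the "flatland" mode: the volume is a 2-D slice whose
  axes are (x, z), the detector is 1-D, and the source rotates in-plane.
  It exists so that the whole pipeline runs at desk scale; every operator
  is dimension-parametric.
* attenuation is stored in 1/mm; Hounsfield units only at display time,
  ``HU = 1000 * (mu - mu_w) / mu_w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScanGeometry", "VolumeGrid", "Volume", "ProjectionSet", "mu_to_hu", "MU_WATER"]

#: default water attenuation (1/mm) used for HU conversion, roughly the
#: narrow-beam value at CBCT effective energies (~60 keV).
MU_WATER = 0.0192


def mu_to_hu(mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    return 1000.0 * (np.asarray(mu) - mu_water) / mu_water


@dataclass
class ScanGeometry:
    """Divergent-beam acquisition description (distances in mm, angles in deg)."""

    sad: float
    sdd: float
    n_u: int
    du: float
    angles: np.ndarray
    times: np.ndarray
    n_v: int = 1
    dv: float = 1.0
    detector_offset_u: float = 0.0
    fan_mode: str = "full"
    ndim: int = 3

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if not (self.sdd > self.sad > 0):
            raise ValueError("require sdd > sad > 0")
        if self.du <= 0 or self.dv <= 0:
            raise ValueError("detector pixel pitches must be > 0")
        if self.angles.shape != self.times.shape or self.angles.ndim != 1:
            raise ValueError("angles and times must be 1-D and equally long")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.fan_mode not in ("full", "half"):
            raise ValueError(f"unknown fan_mode {self.fan_mode!r}")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if self.ndim == 2 and self.n_v != 1:
            raise ValueError("flatland mode uses a 1-D detector (n_v == 1)")

    @property
    def n_frames(self) -> int:
        return len(self.angles)

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return (self.n_u,) if self.ndim == 2 else (self.n_v, self.n_u)

    def u_coords(self) -> np.ndarray:
        """Detector u pixel-center coordinates (mm, on the detector plane)."""
        return (np.arange(self.n_u) - (self.n_u - 1) / 2.0) * self.du + self.detector_offset_u

    def v_coords(self) -> np.ndarray:
        return (np.arange(self.n_v) - (self.n_v - 1) / 2.0) * self.dv


@dataclass
class VolumeGrid:
    """A regular voxel grid: ``shape`` voxels of size ``spacing`` mm.

    ``origin`` is the world coordinate of the *center* of voxel (0, ..., 0).
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] | None = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.shape) != len(self.spacing):
            raise ValueError("shape and spacing dimensionality mismatch")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            # center the grid on the world origin
            self.origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(self.shape, self.spacing))
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (n_voxels, ndim)."""
        axes = [self.axis_coords(i) for i in range(self.ndim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def extent(self) -> np.ndarray:
        """Physical size along each axis (mm, voxel-edge to voxel-edge)."""
        return np.array([n * d for n, d in zip(self.shape, self.spacing)])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(self.origin) - np.array(self.spacing) / 2.0
        return lo, lo + self.extent()

    def upsample(self, factor: int = 2) -> "VolumeGrid":
        """A grid covering the same physical box with ``factor`` x voxels per axis."""
        new_shape = tuple(n * factor for n in self.shape)
        new_spacing = tuple(d / factor for d in self.spacing)
        lo, _ = self.bounds()
        new_origin = tuple(l + d / 2.0 for l, d in zip(lo, new_spacing))
        return VolumeGrid(new_shape, new_spacing, new_origin)

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Volume:
    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels")


@dataclass
class ProjectionSet:
    """Time-ordered stack of line-integral projections."""

    geometry: ScanGeometry
    frames: np.ndarray  # (n_frames, n_v, n_u) or (n_frames, n_u) in flatland

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        expected = (self.geometry.n_frames,) + self.geometry.frame_shape
        if self.frames.shape != expected:
            raise ValueError(f"frames shape {self.frames.shape} != expected {expected}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("projections contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.geometry.n_frames
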