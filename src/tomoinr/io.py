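"""File I/O: volumes, projection sets and raw-intensity preprocessing.

Volumes are written as NIfTI (spacing and origin preserved in the affine);
projection stacks as a NIfTI array with a human-readable YAML sidecar
(``<stem>.geometry.yaml``) carrying every scan-geometry field, so a
projection file plus its sidecar fully determines the projector.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import yaml

from .geometry import ProjectionSet, ScanGeometry, Volume, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "write_projection_set",
    "read_projection_set",
    "preprocess_projections",
    "sidecar_path",
]


def write_volume(vol: Volume, path) -> str:
    path = str(path)
    affine = np.eye(4)
    nd = vol.grid.ndim
    for i in range(nd):
        affine[i, i] = vol.grid.spacing[i]
        affine[i, 3] = vol.grid.origin[i]
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vol.grid.spacing) + (1.0,) * (len(img.shape) - nd))
    nib.save(img, path)
    return path


def read_volume(path) -> Volume:
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    nd = data.ndim
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(nd))
    origin = tuple(float(affine[i, 3]) for i in range(nd))
    grid = VolumeGrid(data.shape, spacing, origin)
    return Volume(grid, data)  # Volume validates finiteness


def sidecar_path(path) -> str:
    base = str(path)
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return base + ".geometry.yaml"


def _geometry_to_dict(g: ScanGeometry) -> dict:
    return {
        "sad_mm": float(g.sad),
        "sdd_mm": float(g.sdd),
        "n_u": int(g.n_u),
        "n_v": int(g.n_v),
        "du_mm": float(g.du),
        "dv_mm": float(g.dv),
        "detector_offset_u_mm": float(g.detector_offset_u),
        "fan_mode": g.fan_mode,
        "angles_deg": [float(a) for a in g.angles],
        "times_s": [float(t) for t in g.times],
        "ndim": int(g.ndim),
    }


def _geometry_from_dict(d: dict) -> ScanGeometry:
    return ScanGeometry(
        sad=d["sad_mm"], sdd=d["sdd_mm"], n_u=d["n_u"], n_v=d["n_v"],
        du=d["du_mm"], dv=d["dv_mm"],
        detector_offset_u=d["detector_offset_u_mm"], fan_mode=d["fan_mode"],
        angles=np.asarray(d["angles_deg"], dtype=np.float64),
        times=np.asarray(d["times_s"], dtype=np.float64),
        ndim=d["ndim"],
    )


def write_projection_set(pset: ProjectionSet, path) -> str:
    """Projections as a NIfTI stack plus the geometry sidecar."""
    path = str(path)
    img = nib.Nifti1Image(np.asarray(pset.frames, dtype=np.float32), np.eye(4))
    nib.save(img, path)
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(_geometry_to_dict(pset.geometry), fh, sort_keys=False)
    return path


def read_projection_set(path) -> ProjectionSet:
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sc = sidecar_path(path)
    if not os.path.exists(sc):
        raise FileNotFoundError(f"missing geometry sidecar {sc}")
    with open(sc) as fh:
        geom = _geometry_from_dict(yaml.safe_load(fh))
    frames = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
    return ProjectionSet(geom, frames)


def preprocess_projections(
    raw_intensities: np.ndarray, air_scan: np.ndarray, geometry: ScanGeometry
) -> ProjectionSet:
    """Air-normalize and log-transform raw detector intensities.

    Per pixel: ``p = ln(air / max(raw, 1))``; zero-valued (dead) pixels are
    overridden to one before the log so the transform stays defined, and
    values are clipped at zero (raw counts above the air scan arise only
    from noise).  Monotone non-increasing in the raw intensity.
    """
    raw = np.asarray(raw_intensities, dtype=np.float64)
    air = np.asarray(air_scan, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("negative raw intensities")
    if np.any(air <= 0):
        raise ValueError("air scan must be strictly positive")
    air_b = np.broadcast_to(air, raw.shape)
    frames = np.log(air_b / np.maximum(raw, 1.0))
    frames = np.maximum(frames, 0.0)
    expected = (geometry.n_frames,) + geometry.frame_shape
    if frames.shape != expected:
        raise ValueError(f"intensity stack shape {frames.shape} != {expected}")
    return ProjectionSet(geometry, frames)
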