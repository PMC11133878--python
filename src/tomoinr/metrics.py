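"""Quantitative evaluation: image metrics, mask propagation, trajectory
extraction and projection-space motion verification.

Volumetric accuracy uses the per-frame relative error (ratio of L2 norms)
and SSIM; motion accuracy uses tumor center-of-mass error (COME) and Dice
after propagating a reference contour with the solved displacement fields.
For data without volumetric ground truth, motion is verified in projection
space: the dynamic reconstruction is re-projected into DRRs and structures
are tracked on both the measured projections and the DRRs (Amsterdam-Shroud
diaphragm extraction or template correlation tracking), compared by Pearson
correlation and an SI localization error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import medfilt
from scipy.stats import pearsonr
from skimage.metrics import structural_similarity

from .geometry import ProjectionSet, ScanGeometry, Volume, VolumeGrid
from .projector import ProjectorConfig, forward_project

__all__ = [
    "relative_error",
    "ssim_volume",
    "propagate_mask",
    "com_error",
    "dice",
    "pearson",
    "center_of_mass",
    "segment_largest_blob",
    "reproject_drr",
    "amsterdam_shroud",
    "track_feature_template",
    "localization_error",
    "MetricReport",
]


# ---------------------------------------------------------------------------
# image-domain metrics
# ---------------------------------------------------------------------------


def relative_error(recon_seq, truth_seq) -> float:
    """Mean over frames of ||recon - truth||_2 / ||truth||_2 (voxel L2 norms)."""
    res = []
    for a, b in zip(recon_seq, truth_seq, strict=True):
        a = a.values if isinstance(a, Volume) else np.asarray(a)
        b = b.values if isinstance(b, Volume) else np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("grid mismatch")
        denom = float((b**2).sum())
        if denom == 0:
            raise ValueError("all-zero ground-truth frame")
        res.append(np.sqrt(float(((a - b) ** 2).sum()) / denom))
    return float(np.mean(res))


def ssim_volume(a, b, data_range: float | None = None) -> float:
    """SSIM with an 11-wide Gaussian window (sigma 1.5), volume-averaged."""
    a = a.values if isinstance(a, Volume) else np.asarray(a)
    b = b.values if isinstance(b, Volume) else np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if data_range <= 0:
        raise ValueError("dynamic range must be positive")
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False,
        )
    )


# ---------------------------------------------------------------------------
# masks and trajectories
# ---------------------------------------------------------------------------


def propagate_mask(ref_mask: np.ndarray, dvf: np.ndarray, spacing) -> np.ndarray:
    """Pull-warp a binary mask with a displacement field (mm), threshold 0.5.

    ``dvf`` has shape (*mask.shape, ndim): the propagated mask at voxel x is
    the reference mask sampled at x + d(x).
    """
    ref_mask = np.asarray(ref_mask)
    dvf = np.asarray(dvf)
    if dvf.shape[:-1] != ref_mask.shape or dvf.shape[-1] != ref_mask.ndim:
        raise ValueError("DVF grid does not match the mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    idx = np.indices(ref_mask.shape).astype(np.float64)
    coords = [idx[k] + dvf[..., k] / spacing[k] for k in range(ref_mask.ndim)]
    vals = ndimage.map_coordinates(ref_mask.astype(np.float64), coords, order=1, mode="constant")
    return vals > 0.5


def center_of_mass(mask: np.ndarray, spacing, origin=None) -> np.ndarray:
    """Intensity-weighted centroid in world mm."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    com_idx = np.array(ndimage.center_of_mass(mask))
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.zeros(mask.ndim) if origin is None else np.asarray(origin, dtype=np.float64)
    return origin + com_idx * spacing


def com_error(mask_a: np.ndarray, mask_b: np.ndarray, spacing):
    """Per-axis and Euclidean centroid distance (mm) between two masks."""
    ca = center_of_mass(mask_a, spacing)
    cb = center_of_mass(mask_b, spacing)
    diff = ca - cb
    return diff, float(np.linalg.norm(diff))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("grid mismatch")
    s = mask_a.sum() + mask_b.sum()
    if s == 0:
        raise ValueError("both masks empty")
    return float(2.0 * np.logical_and(mask_a, mask_b).sum() / s)


def pearson(traj_a, traj_b) -> float:
    a = np.asarray(traj_a, dtype=np.float64)
    b = np.asarray(traj_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("trajectories must match and have length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance trajectory")
    return float(pearsonr(a, b)[0])


def segment_largest_blob(volume, threshold: float, roi_mask: np.ndarray | None = None):
    """Threshold a (reconstructed) volume and keep the largest connected
    component, optionally within a region of interest."""
    vals = volume.values if isinstance(volume, Volume) else np.asarray(volume)
    seg = vals > threshold
    if roi_mask is not None:
        seg &= roi_mask
    labels, n = ndimage.label(seg)
    if n == 0:
        return seg
    sizes = ndimage.sum(seg, labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


# ---------------------------------------------------------------------------
# projection-space verification
# ---------------------------------------------------------------------------


def reproject_drr(state, geometry: ScanGeometry | None = None,
                  config: ProjectorConfig | None = None) -> ProjectionSet:
    """Re-project every reconstructed frame into a DRR at its own gantry angle."""
    geom = geometry or state.geometry
    if geom.n_frames != state.geometry.n_frames:
        raise ValueError("geometry frame count mismatch")
    frames = np.empty((geom.n_frames,) + geom.frame_shape)
    for t in range(geom.n_frames):
        vol, _ = state.render_frame(t)
        frames[t] = forward_project(vol, geom, t, config)
    return ProjectionSet(geom, frames)


def amsterdam_shroud(pset: ProjectionSet, band: tuple[int, int] | None = None,
                     zscore: bool = False):
    """Amsterdam-Shroud image and a craniocaudal motion trajectory.

    Each projection is differentiated along the craniocaudal (detector row)
    axis and collapsed across the lateral axis; the per-frame profiles are
    stacked into a (n_rows, n_frames) image.  The per-frame position is the
    gradient-energy centroid within ``band`` -- sub-row precision, since
    divergent beams blur a moving interface over a few rows -- median
    filtered over 5 frames.  Requires a 2-D detector (3-D scans).
    """
    if pset.geometry.ndim != 3:
        raise ValueError("the shroud needs a 2-D detector (3-D scan)")
    n_v = pset.geometry.n_v
    profiles = np.diff(pset.frames, axis=1).sum(axis=2)  # (n_frames, n_v-1)
    shroud = profiles.T  # rows x frames
    if zscore:
        sd = shroud.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        shroud = (shroud - shroud.mean(axis=0, keepdims=True)) / sd
    if band is None:
        band = (0, shroud.shape[0])
    lo, hi = band
    if not (0 <= lo < hi <= shroud.shape[0]):
        raise ValueError("band outside the detector")
    g2 = shroud[lo:hi] ** 2
    denom = g2.sum(axis=0)
    denom[denom == 0] = 1.0
    rows = lo + (np.arange(lo, hi)[:, None] - lo) * g2 / denom[None, :]
    traj = medfilt(rows.sum(axis=0), 5)
    return shroud, traj


def track_feature_template(
    pset_a: ProjectionSet,
    pset_b: ProjectionSet,
    template_center: tuple[int, int],
    template_half: int = 6,
    search_half: int = 20,
    min_correlation: float = 0.3,
):
    """Track one template down both projection sets by normalized
    cross-correlation along the craniocaudal axis.

    A single template is cut from frame 0 of ``pset_a`` around
    ``template_center`` (row, col) and searched in *both* sets, so a
    systematic SI offset between the sets shows up as a track difference.
    Per frame, the SI position of the best match within a vertical search
    band is recorded; frames whose peak correlation falls below
    ``min_correlation`` are marked missing (NaN).
    """
    r0, c0 = template_center
    tpl = pset_a.frames[0, r0 - template_half : r0 + template_half + 1,
                        c0 - template_half : c0 + template_half + 1]
    tpl = tpl - tpl.mean()
    tnorm = np.sqrt((tpl**2).sum())

    def _track(pset):
        frames = pset.frames
        out = np.full(len(frames), np.nan)
        for t in range(len(frames)):
            best, best_r = -np.inf, np.nan
            for dr in range(-search_half, search_half + 1):
                r = r0 + dr
                if r - template_half < 0 or r + template_half + 1 > frames.shape[1]:
                    continue
                win = frames[t, r - template_half : r + template_half + 1,
                             c0 - template_half : c0 + template_half + 1]
                w = win - win.mean()
                denom = np.sqrt((w**2).sum()) * tnorm
                if denom == 0:
                    continue
                score = float((w * tpl).sum() / denom)
                if score > best:
                    best, best_r = score, r
            if best >= min_correlation:
                out[t] = best_r
        return out

    return _track(pset_a), _track(pset_b)


def localization_error(tracks_a, tracks_b, pixel_mm: float = 1.0,
                       demagnify: float | None = None) -> float:
    """Root of the doubly averaged squared SI differences between matched
    point tracks (detector-plane mm unless ``demagnify`` = SDD/SAD given).

    ``tracks_a/b``: arrays (n_frames,) or (n_frames, n_points); NaNs mark
    missing points and are excluded pairwise.
    """
    a = np.atleast_2d(np.asarray(tracks_a, dtype=np.float64).T).T
    b = np.atleast_2d(np.asarray(tracks_b, dtype=np.float64).T).T
    if a.shape != b.shape:
        raise ValueError("track sets must match")
    per_frame = []
    for p in range(a.shape[0]):
        valid = ~(np.isnan(a[p]) | np.isnan(b[p]))
        if valid.any():
            per_frame.append(np.mean((a[p, valid] - b[p, valid]) ** 2))
    if not per_frame:
        raise ValueError("no matched points")
    le = float(np.sqrt(np.mean(per_frame))) * pixel_mm
    if demagnify:
        le /= demagnify
    return le


def segment_reference_tumor(state, phantom, grid: VolumeGrid | None = None) -> np.ndarray:
    """Contour the tumor on the solved reference frame.

    Stands in for manual contouring: voxels above the lung/tumor midpoint
    attenuation, well inside the host lung, grouped into connected
    components; the component whose area/volume is closest to that of the
    known tumor diameter is kept.  The reference phase is free in this
    reconstruction, so the prior is only the host-lung region and the tumor
    size, not the tumor position.
    """
    from .phantom import MU_LUNG, MU_TUMOR

    grid = grid or state.grid_high
    ref = state.reference(grid).values
    pts = grid.voxel_centers()
    if phantom.moving_region == "tumor":
        # physical-phantom analog: the tumor can only sit on the rod corridor
        roi = (phantom.motion_weight(pts) > 0.5).reshape(grid.shape)
    else:
        host = phantom.lungs[1]
        roi = (host.rho(pts) < 0.95).reshape(grid.shape)
    seg = (ref > 0.5 * (MU_LUNG + MU_TUMOR)) & roi
    labels, n = ndimage.label(seg)
    if n == 0:
        return seg
    expected = phantom.tumor.inside(pts).sum()
    sizes = ndimage.sum(seg, labels, range(1, n + 1))
    return labels == (1 + int(np.argmin(np.abs(sizes - expected))))


def evaluate_dynamic(state, phantom, frames=None, compute_ssim: bool = False):
    """Score a dynamic reconstruction against the phantom's exact truth.

    Per frame: render the solved volume (relative error, optional SSIM),
    propagate the reference tumor contour with the solved DVF, and compare
    against the ground-truth mask (COM error, Dice).  Returns a
    :class:`MetricReport` plus the solved and true SI trajectories (mm).
    """
    from .phantom import render_dynamic_volume

    grid = phantom.grid
    n_frames = phantom.trace.n_frames
    frames = range(n_frames) if frames is None else frames
    seg_ref = segment_reference_tumor(state, phantom, grid)
    res, ssims, comes, dscs, si_s, si_t = [], [], [], [], [], []
    for t in frames:
        vol_t, dvf_t = state.render_frame(t, grid)
        gt_vol, gt_mask = render_dynamic_volume(phantom, t)
        res.append(relative_error([vol_t], [gt_vol]))
        if compute_ssim:
            ssims.append(ssim_volume(vol_t, gt_vol))
        m_t = propagate_mask(seg_ref, dvf_t, grid.spacing)
        if m_t.sum() == 0 or gt_mask.sum() == 0:
            continue
        _, d3 = com_error(m_t, gt_mask, grid.spacing)
        comes.append(d3)
        dscs.append(dice(m_t, gt_mask))
        si_s.append(center_of_mass(m_t, grid.spacing)[-1])
        si_t.append(center_of_mass(gt_mask, grid.spacing)[-1])
    report = MetricReport(
        re_mean=float(np.mean(res)), re_sd=float(np.std(res)),
        come_mean=float(np.mean(comes)), come_sd=float(np.std(comes)),
        dsc_mean=float(np.mean(dscs)), dsc_sd=float(np.std(dscs)),
        pearson_si=(
            pearson(si_s, si_t)
            if len(si_s) > 1 and np.std(si_s) > 0 and np.std(si_t) > 0
            else np.nan
        ),
        n_frames_evaluated=len(comes),
    )
    if compute_ssim:
        report.ssim_mean = float(np.mean(ssims))
        report.ssim_sd = float(np.std(ssims))
    return report, np.asarray(si_s), np.asarray(si_t)


@dataclass
class MetricReport:
    """Summary statistics of a dynamic-reconstruction evaluation."""

    re_mean: float = np.nan
    re_sd: float = np.nan
    ssim_mean: float = np.nan
    ssim_sd: float = np.nan
    come_mean: float = np.nan
    come_sd: float = np.nan
    dsc_mean: float = np.nan
    dsc_sd: float = np.nan
    pearson_si: float = np.nan
    le: float = np.nan
    n_frames_evaluated: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)
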