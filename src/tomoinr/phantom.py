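"""Dynamic digital thorax phantom with analytically known motion.

The reference anatomy is built from analytic ellipsoids (body, two lungs, a
spine surrogate, a diaphragm-like lung base, and a spherical tumor) at the
scale of a thoracic CBCT.  The ground-truth deformation is a spatially
weighted translation: the full breathing displacement inside the lungs,
decaying smoothly (cosine ramp) to zero toward the body surface and the
spine.  This gives a closed-form, smooth displacement field whose pull
convention matches the reconstruction model, so rendered volumes, tumor
masks and DVFs are exact at any time.

Six free-breathing scenarios are provided: X1 quasi-periodic (~5 s cycle),
X2 with a ~5 mm baseline step near mid-scan, X3 amplitude variation +
baseline shift, X4 period and amplitude drifting upward, X5 a single
breathing cycle spanning the whole scan, X6 combined irregularity -- plus a
static control and a "cirs"-style variant in which only the tumor moves
inside a static body (physical-phantom analog).

In flatland (2-D) mode the slice axes are (x = left-right, z =
superior-inferior) and the source rotates in-plane, so the dominant
breathing direction stays inside the imaging plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ProjectionSet, ScanGeometry, Volume, VolumeGrid
from .projector import ProjectorConfig, forward_project

__all__ = [
    "MotionTrace",
    "DynamicPhantom",
    "make_motion_trace",
    "make_thorax_phantom",
    "make_scan_geometry",
    "render_dynamic_volume",
    "simulate_scan",
    "SCENARIOS",
]

# attenuation analogs (1/mm): air < lung < soft tissue < bone
MU_AIR = 0.0
MU_LUNG = 0.004
MU_SOFT = 0.02
MU_TUMOR = 0.024
MU_BONE = 0.038

SCENARIOS = ("X1", "X2", "X3", "X4", "X5", "X6", "static", "custom")


@dataclass
class MotionTrace:
    """Displacement of the moving anatomy vs the reference frame (mm)."""

    duration: float
    fps: float
    times: np.ndarray  # (n_frames,), s
    lr: np.ndarray
    ap: np.ndarray
    si: np.ndarray
    scenario: str = "custom"

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def displacement(self, frame: int, ndim: int = 3) -> np.ndarray:
        """Motion vector at a frame: (lr, si) in flatland, (lr, ap, si) in 3-D."""
        if ndim == 2:
            return np.array([self.lr[frame], self.si[frame]])
        return np.array([self.lr[frame], self.ap[frame], self.si[frame]])


def _cycle_waveform(u: np.ndarray) -> np.ndarray:
    """One breathing cycle on u in [0,1): 0 at end-exhale, 1 at end-inhale."""
    return np.sin(np.pi * u) ** 4


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_motion_trace(
    scenario: str,
    duration: float = 60.0,
    fps: float = 11.0,
    seed: int = 0,
    amplitude: float = 13.0,
    period: float = 5.0,
    ap_ratio: float = 0.3,
    lr_ratio: float = 0.1,
    baseline_shift: float = 5.0,
    baseline_time: float = 30.0,
) -> MotionTrace:
    """Breathing trace for one of the supported scenarios.

    ``amplitude`` is the SI peak-to-trough excursion (mm) of the driven
    structures; AP/LR components are fixed fractions of SI (the digital
    anatomy only pins the SI range, so the transverse ratios are explicit,
    configurable parameters).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    n = int(round(duration * fps))
    times = np.arange(n) / fps
    rng = np.random.default_rng(seed)

    if scenario == "static":
        zero = np.zeros(n)
        return MotionTrace(duration, fps, times, zero, zero.copy(), zero.copy(), scenario)

    amp_jitter = {"X1": 0.05, "X2": 0.05, "X3": 0.25, "X4": 0.0, "X6": 0.25}.get(scenario, 0.05)
    per_jitter = {"X1": 0.03, "X2": 0.03, "X3": 0.05, "X4": 0.0, "X6": 0.12}.get(scenario, 0.03)

    b = np.zeros(n)
    if scenario == "X5":
        # exactly one slow cycle over the scan
        b = amplitude * _cycle_waveform(times / duration)
    else:
        t0 = 0.0
        c = 0
        n_cycles_est = max(int(np.ceil(duration / period)) + 2, 3)
        while t0 < duration:
            if scenario == "X4":
                frac = t0 / duration
                T_c = 4.0 + 2.5 * frac  # period gradually increasing
                A_c = amplitude * (0.85 + 0.45 * frac)  # amplitude growing with it
            else:
                T_c = period * (1.0 + per_jitter * rng.uniform(-1, 1))
                A_c = amplitude * (1.0 + amp_jitter * rng.uniform(-1, 1))
            sel = (times >= t0) & (times < t0 + T_c)
            b[sel] = A_c * _cycle_waveform((times[sel] - t0) / T_c)
            t0 += T_c
            c += 1
            if c > 10 * n_cycles_est:  # safety for degenerate params
                break

    baseline = np.zeros(n)
    if scenario in ("X2", "X3", "X6"):
        baseline += baseline_shift * _sigmoid((times - baseline_time) / 1.5)
    if scenario == "X6":
        baseline += 3.0 * times / duration  # slow drift on top of the step

    si = -(b + baseline)  # inferior displacement during inhale
    ap = ap_ratio * (-si)
    lr = lr_ratio * (-si)
    return MotionTrace(duration, fps, times, lr, ap, si, scenario)


@dataclass
class _Ellipsoid:
    center: np.ndarray
    semiaxes: np.ndarray
    mu: float

    def inside(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - self.center) / self.semiaxes
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def rho(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - self.center) / self.semiaxes
        return np.sqrt(np.einsum("ij,ij->i", q, q))


@dataclass
class DynamicPhantom:
    """Analytic reference anatomy + motion trace + exact ground-truth DVFs."""

    grid: VolumeGrid
    body: _Ellipsoid
    lungs: list
    spine: _Ellipsoid
    tumor: _Ellipsoid
    trace: MotionTrace | None
    moving_region: str  # "lungs" or "tumor"
    ramp_band_mm: float
    reference: Volume = None
    tumor_mask_ref: np.ndarray = None

    @property
    def ndim(self) -> int:
        return self.grid.ndim

    # -- analytic fields ---------------------------------------------------
    def mu_at(self, pts: np.ndarray) -> np.ndarray:
        """Reference attenuation at arbitrary world points (n, d) -> (n,)."""
        pts = np.atleast_2d(pts)
        mu = np.zeros(len(pts))
        mu[self.body.inside(pts)] = MU_SOFT
        for lung in self.lungs:
            mu[lung.inside(pts)] = MU_LUNG
        mu[self.spine.inside(pts)] = MU_BONE
        mu[self.tumor.inside(pts)] = MU_TUMOR
        return mu

    def tumor_at(self, pts: np.ndarray) -> np.ndarray:
        return self.tumor.inside(np.atleast_2d(pts)).astype(np.float64)

    def motion_weight(self, pts: np.ndarray) -> np.ndarray:
        """Smooth weight in [0, 1]: 1 on the moving core, 0 at body surface/spine."""
        pts = np.atleast_2d(pts)
        if self.moving_region == "tumor":
            # rod-like analog: the weight is 1 on a capsule along the tumor's
            # swept path (so only the rod corridor moves, not the whole body)
            a = self.tumor.center
            b = a.copy()
            if self.trace is not None and len(self.trace.si):
                t_star = int(np.argmax(np.abs(self.trace.si)))
                b = a + self.trace.displacement(t_star, self.ndim)
            ab = b - a
            denom = float(ab @ ab)
            if denom > 0:
                s = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            else:
                s = np.zeros(len(pts))
            closest = a[None, :] + s[:, None] * ab[None, :]
            r = np.linalg.norm(pts - closest, axis=1)
            return _cos_ramp(r, self.tumor.semiaxes[0] + 5.0, self.ramp_band_mm)
        w = np.zeros(len(pts))
        for lung in self.lungs:
            rho = lung.rho(pts)
            d_eff = (rho - 0.98) * float(np.min(lung.semiaxes))
            w_l = _cos_ramp_d(d_eff, self.ramp_band_mm)
            w = 1.0 - (1.0 - w) * (1.0 - w_l)
        # suppress motion over the spine surrogate
        rho_s = self.spine.rho(pts)
        d_s = (rho_s - 1.0) * float(np.min(self.spine.semiaxes))
        w = w * (1.0 - _cos_ramp_d(d_s, self.ramp_band_mm))
        return w

    def dvf_truth(self, frame: int, pts: np.ndarray | None = None) -> np.ndarray:
        """Exact pull-convention displacement (mm) at world points (default:
        voxel centers), shape (n, d): I(x, t) = I_ref(x + d(x, t))."""
        if self.trace is None:
            raise ValueError("phantom has no motion trace attached")
        if not 0 <= frame < self.trace.n_frames:
            raise ValueError(f"frame {frame} outside scan")
        if pts is None:
            pts = self.grid.voxel_centers()
        m = self.trace.displacement(frame, self.ndim)
        w = self.motion_weight(pts)
        return -w[:, None] * m[None, :]


def _cos_ramp(r: np.ndarray, core: float, band: float) -> np.ndarray:
    """1 for r <= core, cosine-squared falloff over ``band``, then 0."""
    return _cos_ramp_d(r - core, band)


def _cos_ramp_d(d: np.ndarray, band: float) -> np.ndarray:
    out = np.zeros_like(np.asarray(d, dtype=np.float64))
    out[d <= 0] = 1.0
    ramp = (d > 0) & (d < band)
    out[ramp] = np.cos(0.5 * np.pi * d[ramp] / band) ** 2
    return out


def make_thorax_phantom(
    shape,
    spacing,
    tumor_diameter: float = 30.0,
    seed: int = 0,
    moving_region: str = "lungs",
    ramp_band_mm: float = 20.0,
    trace: MotionTrace | None = None,
) -> DynamicPhantom:
    """Build the reference anatomy (deterministic for a fixed seed).

    ``shape``/``spacing`` follow the grid axes: (x, z) in flatland,
    (x, y, z) in 3-D.  The tumor is a sphere of ``tumor_diameter`` mm placed
    in the lower portion of the right lung; it must fit inside the lung.
    """
    grid = VolumeGrid(tuple(shape), tuple(spacing))
    d = grid.ndim
    rng = np.random.default_rng(seed)
    ext = grid.extent()
    jitter = lambda s: 1.0 + 0.02 * s * rng.uniform(-1, 1)

    if d == 2:
        ex, ez = ext
        body = _Ellipsoid(np.zeros(2), np.array([0.46 * ex * jitter(1), 0.48 * ez * jitter(1)]), MU_SOFT)
        lung_dx = 0.21 * ex
        lung_ax = np.array([0.17 * ex * jitter(1), 0.33 * ez * jitter(1)])
        lungs = [
            _Ellipsoid(np.array([-lung_dx, 0.05 * ez]), lung_ax, MU_LUNG),
            _Ellipsoid(np.array([+lung_dx, 0.05 * ez]), lung_ax.copy(), MU_LUNG),
        ]
        spine = _Ellipsoid(np.zeros(2), np.array([0.035 * ex, 0.46 * ez]), MU_BONE)
        # lower-lobe placement for breathing anatomy; the physical-phantom
        # analog (tumor-only motion) centers the rod in the lung insert
        drop = 0.0 if moving_region == "tumor" else -0.25 * lung_ax[1]
        tumor_c = lungs[1].center + np.array([0.02 * ex, drop])
    else:
        ex, ey, ez = ext
        body = _Ellipsoid(
            np.zeros(3),
            np.array([0.46 * ex * jitter(1), 0.40 * ey * jitter(1), 0.48 * ez * jitter(1)]),
            MU_SOFT,
        )
        lung_dx = 0.21 * ex
        lung_ax = np.array([0.17 * ex * jitter(1), 0.26 * ey * jitter(1), 0.33 * ez * jitter(1)])
        lungs = [
            _Ellipsoid(np.array([-lung_dx, 0.0, 0.05 * ez]), lung_ax, MU_LUNG),
            _Ellipsoid(np.array([+lung_dx, 0.0, 0.05 * ez]), lung_ax.copy(), MU_LUNG),
        ]
        spine = _Ellipsoid(
            np.array([0.0, 0.28 * ey, 0.0]), np.array([0.035 * ex, 0.05 * ey, 0.46 * ez]), MU_BONE
        )
        drop = 0.0 if moving_region == "tumor" else -0.25 * lung_ax[-1]
        tumor_c = lungs[1].center + np.array([0.02 * ex, 0.0, drop])

    r_t = tumor_diameter / 2.0
    tumor = _Ellipsoid(tumor_c, np.full(d, r_t), MU_TUMOR)
    # the tumor (over its full excursion, if a trace is known) must fit in the lung
    host = lungs[1]
    margin = float(np.max(np.abs(trace.si))) if trace is not None else 0.0
    probe = np.array(tumor_c)
    probe[-1] -= margin
    rho_lo = host.rho(probe[None, :])[0]
    if rho_lo + r_t / float(np.min(host.semiaxes)) > 1.0:
        raise ValueError(
            f"tumor (diameter {tumor_diameter} mm, excursion {margin:.1f} mm) "
            "does not fit inside the lung"
        )

    ph = DynamicPhantom(
        grid=grid, body=body, lungs=lungs, spine=spine, tumor=tumor,
        trace=trace, moving_region=moving_region, ramp_band_mm=ramp_band_mm,
    )
    pts = grid.voxel_centers()
    ph.reference = Volume(grid, ph.mu_at(pts).reshape(grid.shape))
    ph.tumor_mask_ref = ph.tumor_at(pts).reshape(grid.shape) > 0.5
    return ph


def make_scan_geometry(
    n_frames: int,
    duration: float = 60.0,
    arc_deg: float = 360.0,
    ndim: int = 3,
    n_u: int = 256,
    du: float = 1.6,
    n_v: int = 192,
    dv: float = 1.6,
    sad: float = 1000.0,
    sdd: float = 1500.0,
    detector_offset_u: float = 0.0,
    fan_mode: str = "full",
) -> ScanGeometry:
    """Uniform-rotation scan: ``n_frames`` over ``arc_deg`` in ``duration`` s."""
    angles = arc_deg * np.arange(n_frames) / n_frames
    times = duration * np.arange(n_frames) / n_frames
    if ndim == 2:
        n_v, dv = 1, 1.0
    return ScanGeometry(
        sad=sad, sdd=sdd, n_u=n_u, du=du, n_v=n_v, dv=dv,
        detector_offset_u=detector_offset_u, fan_mode=fan_mode,
        angles=angles, times=times, ndim=ndim,
    )


def render_dynamic_volume(phantom: DynamicPhantom, frame: int):
    """Exact dynamic volume and tumor mask at a frame (continuous sampling).

    ``I(x, t) = I_ref(x + d_truth(x, t))`` evaluated analytically at voxel
    centers; the mask is warped with the same field and thresholded at 0.5.
    """
    grid = phantom.grid
    pts = grid.voxel_centers()
    if phantom.trace is None or phantom.trace.scenario == "static":
        if phantom.trace is not None and not 0 <= frame < phantom.trace.n_frames:
            raise ValueError(f"frame {frame} outside scan")
        return (
            Volume(grid, phantom.reference.values.copy()),
            phantom.tumor_mask_ref.copy(),
        )
    warped = pts + phantom.dvf_truth(frame, pts)
    vol = Volume(grid, phantom.mu_at(warped).reshape(grid.shape))
    mask = phantom.tumor_at(warped).reshape(grid.shape) > 0.5
    return vol, mask


def simulate_scan(
    phantom: DynamicPhantom,
    geometry: ScanGeometry,
    noise_photons: float | None = None,
    seed: int = 0,
    projector: ProjectorConfig | None = None,
) -> ProjectionSet:
    """Time-stamped scan of the dynamic phantom.

    Frame ``t`` projects the exact dynamic volume at that instant through the
    gantry angle of frame ``t``.  Optional Poisson noise is applied in the
    intensity domain (``I = I0 exp(-p)``) and re-logged.
    """
    if phantom.trace is not None:
        t_scan = geometry.times[-1]
        if t_scan > phantom.trace.duration + 1e-9:
            raise ValueError("scan times exceed the motion-trace duration")
        if geometry.n_frames != phantom.trace.n_frames:
            raise ValueError(
                f"geometry has {geometry.n_frames} frames but trace has "
                f"{phantom.trace.n_frames}"
            )
    frames = np.empty((geometry.n_frames,) + geometry.frame_shape)
    for t in range(geometry.n_frames):
        vol, _ = render_dynamic_volume(phantom, t)
        frames[t] = forward_project(vol, geometry, t, projector)
    if noise_photons is not None:
        rng = np.random.default_rng(seed)
        intensity = noise_photons * np.exp(-frames)
        noisy = rng.poisson(intensity).astype(np.float64)
        frames = np.log(noise_photons / np.maximum(noisy, 1.0))
        frames = np.maximum(frames, 0.0)
    return ProjectionSet(geometry, frames)
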