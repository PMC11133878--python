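"""Evaluation metrics and projection-space motion verification."""

import numpy as np
import pytest

from tomoinr.geometry import ProjectionSet, Volume, VolumeGrid
from tomoinr.metrics import (
    reproject_drr,
    amsterdam_shroud,
    center_of_mass,
    com_error,
    dice,
    localization_error,
    pearson,
    propagate_mask,
    relative_error,
    ssim_volume,
    track_feature_template,
)


class TestRelativeError:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).random((8, 8))
        assert relative_error([a], [a.copy()]) == 0.0

    def test_zero_reconstruction_is_one(self):
        a = np.random.default_rng(0).random((8, 8))
        assert abs(relative_error([np.zeros_like(a)], [a]) - 1.0) < 1e-12

    def test_homogeneous_scaling(self):
        a = np.random.default_rng(0).random((8, 8))
        assert abs(relative_error([1.1 * a], [a]) - 0.1) < 1e-12

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error([np.ones((4, 4))], [np.zeros((4, 4))])


class TestSSIM:
    def test_identity_is_one(self):
        a = np.random.default_rng(1).random((32, 32))
        assert ssim_volume(a, a.copy(), data_range=1.0) == 1.0

    def test_inversion_scores_low(self):
        a = (np.random.default_rng(2).random((32, 32)) > 0.5).astype(np.float64)
        assert ssim_volume(a, 1.0 - a, data_range=1.0) < 0.5

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert ssim_volume(a, b, 1.0) == ssim_volume(b, a, 1.0)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            ssim_volume(np.zeros((16, 16)), np.zeros((16, 16)), data_range=0.0)


class TestMaskMetrics:
    def _ball(self, center, r=6, n=32):
        idx = np.indices((n, n))
        return ((idx[0] - center[0]) ** 2 + (idx[1] - center[1]) ** 2) <= r * r

    def test_propagate_zero_dvf_is_identity(self):
        m = self._ball((16, 16))
        out = propagate_mask(m, np.zeros(m.shape + (2,)), (2.0, 2.0))
        assert np.array_equal(out, m)

    def test_propagate_constant_shift_moves_against_pull(self):
        m = self._ball((16, 16))
        dvf = np.zeros(m.shape + (2,))
        dvf[..., 0] = 4.0  # +4 mm pull => contents move -2 voxels at 2 mm
        out = propagate_mask(m, dvf, (2.0, 2.0))
        c0 = center_of_mass(m, (2.0, 2.0))
        c1 = center_of_mass(out, (2.0, 2.0))
        assert abs((c1 - c0)[0] + 4.0) < 1.0

    def test_volume_conserved_under_translation(self):
        m = self._ball((16, 16))
        dvf = np.zeros(m.shape + (2,))
        dvf[..., 1] = 4.6  # generic sub-voxel shift (2.3 voxels)
        out = propagate_mask(m, dvf, (2.0, 2.0))
        assert abs(out.sum() - m.sum()) / m.sum() < 0.05

    def test_com_error_axis_and_euclidean(self):
        m = self._ball((12, 12))
        shifted_z = np.roll(m, 2, axis=1)
        _, d = com_error(m, shifted_z, (2.0, 2.0))
        assert abs(d - 4.0) < 1e-9
        m345 = np.roll(np.roll(self._ball((12, 12)), 3, axis=0), 4, axis=1)
        diff, d = com_error(self._ball((12, 12)), m345, (1.0, 1.0))
        assert abs(d - 5.0) < 1e-9

    def test_com_error_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            com_error(np.zeros((8, 8), bool), self._ball((4, 4), 2, 8), (1.0, 1.0))

    def test_dice_identity_disjoint_half(self):
        m = self._ball((10, 10), 5)
        assert dice(m, m) == 1.0
        assert dice(m, np.roll(m, 16, axis=0)) == 0.0
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:4, :2] = True  # 8 px
        b[2:6, :2] = True  # 8 px, overlap 4
        assert dice(a, b) == 0.5

    def test_dice_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


class TestPearson:
    def test_identity_and_negation(self):
        x = np.random.default_rng(4).standard_normal(50)
        assert abs(pearson(x, x) - 1.0) < 1e-12
        assert abs(pearson(x, -x) + 1.0) < 1e-12

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


class TestLocalizationError:
    def test_identity_is_zero(self):
        t = np.random.default_rng(5).random(20)
        assert localization_error(t, t.copy()) == 0.0

    def test_constant_offset(self):
        t = np.random.default_rng(5).random(20)
        assert abs(localization_error(t, t + 3.0) - 3.0) < 1e-12

    def test_single_point_formula(self):
        assert localization_error([5.0], [2.0]) == 3.0

    def test_missing_points_excluded(self):
        a = np.array([1.0, np.nan, 2.0])
        b = np.array([1.0, 99.0, 2.0])
        assert localization_error(a, b) == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            localization_error([np.nan], [np.nan])

    def test_demagnification_flag(self):
        t = np.zeros(5)
        assert localization_error(t, t + 3.0, demagnify=1.5) == 2.0


def _sinusoid_scan_3d(seed=0, n_frames=40, period_s=30.0):
    """Small 3-D scan of a diaphragm-like interface bobbing along z: a body
    cylinder whose lower half is abdomen-dense and upper half lung-light,
    the interface following a sinusoid."""
    from tomoinr.phantom import make_scan_geometry
    from tomoinr.projector import forward_project

    rng = np.random.default_rng(seed)
    grid = VolumeGrid((24, 24, 24), (8.0, 8.0, 8.0))
    geom = make_scan_geometry(n_frames, ndim=3, n_u=32, du=10.0, n_v=48, dv=5.0)
    pts = grid.voxel_centers()
    body = np.linalg.norm(pts[:, :2], axis=1) < 50
    amp_mm = 20.0
    z_traj = amp_mm * np.sin(2 * np.pi * geom.times / period_s + rng.uniform(0, np.pi))
    frames = np.empty((n_frames,) + geom.frame_shape)
    for t in range(n_frames):
        # linear partial volume across the interface so sub-voxel interface
        # positions produce distinct projections
        below_frac = np.clip((z_traj[t] - pts[:, 2]) / 8.0 + 0.5, 0.0, 1.0)
        mu = body * (0.004 + 0.016 * below_frac)
        frames[t] = forward_project(Volume(grid, mu.reshape(grid.shape)), geom, t)
    return ProjectionSet(geom, frames), z_traj


class TestAmsterdamShroud:
    def test_image_dimensions(self):
        pset, _ = _sinusoid_scan_3d()
        shroud, traj = amsterdam_shroud(pset)
        assert shroud.shape == (pset.geometry.n_v - 1, pset.n_frames)
        assert traj.shape == (pset.n_frames,)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_sinusoidal_motion(self, seed):
        pset, z_traj = _sinusoid_scan_3d(seed, n_frames=60)
        _, traj = amsterdam_shroud(pset)
        # detector rows run inferior->superior in v; correlate magnitudes
        assert abs(pearson(traj, z_traj)) >= 0.99

    def test_static_scan_trajectory_flat(self):
        from tomoinr.phantom import make_scan_geometry
        from tomoinr.projector import forward_project

        grid = VolumeGrid((24, 24, 24), (8.0, 8.0, 8.0))
        geom = make_scan_geometry(30, ndim=3, n_u=32, du=10.0, n_v=48, dv=5.0)
        pts = grid.voxel_centers()
        ball = 0.02 * (np.linalg.norm(pts, axis=1) < 60).astype(float).reshape(grid.shape)
        frames = np.stack(
            [forward_project(Volume(grid, ball), geom, t) for t in range(30)]
        )
        _, traj = amsterdam_shroud(ProjectionSet(geom, frames))
        assert traj.std() < 0.2

    def test_band_outside_detector_rejected(self):
        pset, _ = _sinusoid_scan_3d()
        with pytest.raises(ValueError):
            amsterdam_shroud(pset, band=(0, 10**4))


class TestReprojectDRR:
    def _state(self, pset, grid):
        """A reconstruction state with zero motion and an untrained field."""
        from tomoinr.bspline import MotionBasisSet
        from tomoinr.fields import SpatialINR, TemporalINR
        from tomoinr.training import ReconstructionState, TrainingConfig

        rng = np.random.default_rng(0)
        spatial = SpatialINR(grid, rng)
        spatial.encoder.tables.data[:] = rng.uniform(-0.01, 0.01, spatial.encoder.tables.shape)
        temporal = TemporalINR(pset.n_frames, 3, 2, rng)
        for mlp in temporal.mlps:
            for W, b in zip(mlp.weights, mlp.biases):
                W.data[:] = 0.0
                b.data[:] = 0.0
        return ReconstructionState(
            spatial=spatial, temporal=temporal, mbcs=MotionBasisSet(2, (4, 6, 8)),
            config=TrainingConfig(recon_shape=grid.shape, recon_spacing=grid.spacing),
            geometry=pset.geometry, grid_low=grid, grid_high=grid, fov_grid=grid,
        )

    def _setup(self):
        from tomoinr.phantom import make_scan_geometry
        from tomoinr.projector import forward_project

        grid = VolumeGrid((24, 24), (8.0, 8.0))
        geom = make_scan_geometry(12, ndim=2, n_u=32, du=10.0)
        pset = ProjectionSet(geom, np.zeros((12, 32)))
        state = self._state(pset, grid)
        # targets generated from the state's own rendering: a perfect fit
        ref = state.reference(grid)
        frames = np.stack([forward_project(ref, geom, t) for t in range(12)])
        return ProjectionSet(geom, frames), state

    def test_closed_loop_matches_projections(self):
        pset, state = self._setup()
        drr = reproject_drr(state)
        rel = np.linalg.norm(drr.frames - pset.frames) / np.linalg.norm(pset.frames)
        assert rel < 0.01

    def test_drr_count_equals_frame_count(self):
        pset, state = self._setup()
        assert reproject_drr(state).n_frames == pset.n_frames

    def test_static_scene_equal_angles_identical(self):
        from tomoinr.phantom import make_scan_geometry

        grid = VolumeGrid((24, 24), (8.0, 8.0))
        # two full turns: frames i and i+6 share a gantry angle
        geom = make_scan_geometry(12, ndim=2, n_u=32, du=10.0, arc_deg=720.0)
        state = self._state(ProjectionSet(geom, np.zeros((12, 32))), grid)
        drr = reproject_drr(state)
        assert np.allclose(drr.frames[0], drr.frames[6], atol=1e-12)


class TestTemplateTracking:
    def _static_scan(self):
        """Fixed diaphragm interface: ideal for shift-recovery checks."""
        from tomoinr.phantom import make_scan_geometry
        from tomoinr.projector import forward_project

        grid = VolumeGrid((24, 24, 24), (8.0, 8.0, 8.0))
        geom = make_scan_geometry(20, ndim=3, n_u=32, du=10.0, n_v=48, dv=5.0)
        pts = grid.voxel_centers()
        body = np.linalg.norm(pts[:, :2], axis=1) < 80
        mu = np.where(body & (pts[:, 2] < 10.0), 0.02, np.where(body, 0.004, 0.0))
        vol = Volume(grid, mu.reshape(grid.shape))
        frames = np.stack([forward_project(vol, geom, t) for t in range(20)])
        return ProjectionSet(geom, frames)

    def test_identical_sets_identical_tracks(self):
        pset = self._static_scan()
        a, b = track_feature_template(pset, pset, template_center=(26, 16))
        assert np.allclose(a, b, equal_nan=True)
        assert localization_error(a, b) == 0.0

    def test_constant_shift_recovered(self):
        pset = self._static_scan()
        shifted = ProjectionSet(pset.geometry, np.roll(pset.frames, 3, axis=1))
        a, b = track_feature_template(pset, shifted, template_center=(26, 16))
        valid = ~(np.isnan(a) | np.isnan(b))
        assert valid.any()
        assert np.allclose((b - a)[valid], 3.0)

    def test_occluded_frames_marked_missing(self):
        pset = self._static_scan()
        frames = pset.frames.copy()
        frames[5] = 0.0  # feature vanishes entirely in one frame
        a, _ = track_feature_template(
            ProjectionSet(pset.geometry, frames), pset, template_center=(26, 16),
            min_correlation=0.5,
        )
        assert np.isnan(a[5])
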