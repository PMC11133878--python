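"""Losses, stage schedule and the reconstruction driver."""

import numpy as np
import pytest

from tomoinr.autodiff import Tensor
from tomoinr.geometry import VolumeGrid
from tomoinr.phantom import (
    make_motion_trace,
    make_scan_geometry,
    make_thorax_phantom,
    simulate_scan,
)
from tomoinr.training import (
    TrainingConfig,
    build_stage_schedule,
    loss_img,
    loss_prj_static,
    loss_tv,
    run_reconstruction,
)


class TestLossArithmetic:
    def test_img_identity_is_zero(self):
        target = np.random.default_rng(0).random((8, 8))
        assert float(loss_img(Tensor(target.copy()), target).data) == 0.0

    def test_img_constant_offset_is_offset_squared(self):
        target = np.random.default_rng(0).random((8, 8))
        delta = 0.37
        val = float(loss_img(Tensor(target + delta), target).data)
        assert abs(val - delta**2) < 1e-12

    def test_img_matches_direct_mean_square(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 7)), rng.random((6, 7))
        assert abs(float(loss_img(Tensor(a), b).data) - np.mean((a - b) ** 2)) < 1e-10

    def test_tv_constant_is_zero(self):
        assert float(loss_tv(Tensor(np.full((5, 5), 3.2))).data) == 0.0

    def test_tv_half_step_image_hand_computed(self):
        """4x4 image, left half 0 / right half 1: |differences| sum to 4,
        mean over the 16 voxels is 0.25."""
        img = np.zeros((4, 4))
        img[2:, :] = 1.0  # step along axis 0
        assert abs(float(loss_tv(Tensor(img)).data) - 4.0 / 16.0) < 1e-12

    def test_tv_positively_homogeneous(self):
        img = np.random.default_rng(2).random((6, 6))
        a = float(loss_tv(Tensor(img)).data)
        b = float(loss_tv(Tensor(-2.5 * img)).data)
        assert abs(b - 2.5 * a) < 1e-10

    def test_projection_loss_identity_and_scaling(self):
        rng = np.random.default_rng(3)
        frames = rng.random((4, 30)) + 0.5
        assert float(loss_prj_static(Tensor(frames.copy()), frames).data) == 0.0
        eps = 0.01
        val = float(loss_prj_static(Tensor(frames * (1 + eps)), frames).data)
        assert abs(val - eps**2 * np.mean(frames**2)) < 1e-12

    def test_stage_total_compositions(self):
        """Weighted sums follow the printed formulas exactly."""
        l_prj, l_tv, l_mbc = 0.5, 100.0, 1.0
        lam_tv, lam_mbc = 4e-4, 1.0
        assert abs((l_prj + lam_tv * l_tv) - 0.54) < 1e-12  # stage I step 2
        assert abs((0.2 + lam_mbc * l_mbc) - 1.2) < 1e-12  # stage II
        stage3 = 0.2 + lam_tv * l_tv + lam_mbc * l_mbc
        stage2 = 0.2 + lam_mbc * l_mbc
        assert abs(stage3 - (stage2 + lam_tv * l_tv)) < 1e-15


class TestSchedule:
    def test_default_epoch_counts_and_freezing(self):
        sched = build_stage_schedule(TrainingConfig(), ndim=3)
        by_name = {s.name: s for s in sched}
        assert by_name["III"].epochs == 3000
        assert by_name["I.1"].epochs == 600 and by_name["I.2"].epochs == 700
        assert by_name["II.L1"].epochs == 100 and by_name["II.joint"].epochs == 50
        assert by_name["IV.1"].epochs == 1000 and by_name["V"].epochs == 200
        # spatial INR frozen throughout stage II
        for name in ("II.L1", "II.L2", "II.L3", "II.joint"):
            assert "spatial" not in by_name[name].trainable
        # progressive unlock: finer levels appear one at a time
        assert by_name["II.L1"].trainable == ("temporal", "mbc0")
        assert by_name["II.L2"].trainable == ("temporal", "mbc1")
        # stage IV freezes the motion side
        assert by_name["IV.2"].trainable == ("spatial",)
        # learning rates per the printed schedule
        assert by_name["I.1"].lrs["spatial"] == 4e-4
        assert by_name["I.2"].lrs["spatial"] == 4e-5
        assert by_name["III"].lrs["spatial"] == 1e-5
        assert by_name["III"].lrs["temporal"] == 2e-3
        assert by_name["V"].lrs["spatial"] == 1e-4
        # high-scale basis-norm rescaling by the voxel-count ratio
        assert by_name["V"].norm_scale == 1.0 / 8.0

    def test_epoch_scale_contract(self):
        sched = build_stage_schedule(TrainingConfig(epoch_scale=0.1), ndim=2)
        by_name = {s.name: s for s in sched}
        assert by_name["III"].epochs == 300
        assert by_name["II.joint"].epochs == 5  # ceil(50 * 0.1)
        tiny = build_stage_schedule(TrainingConfig(epoch_scale=1e-5), ndim=2)
        assert all(s.epochs >= 1 for s in tiny)

    def test_flatland_norm_scale(self):
        sched = build_stage_schedule(TrainingConfig(), ndim=2)
        assert {s.name: s for s in sched}["V"].norm_scale == 0.25


def _tiny_problem(seed=3, scenario="X1"):
    n = 24
    tr = make_motion_trace(scenario, 60.0, n / 60.0, seed=seed)
    ph = make_thorax_phantom((32, 32), (6.0, 6.0), 30.0, seed=seed, trace=tr)
    geom = make_scan_geometry(n, ndim=2, n_u=48, du=5.0)
    pset = simulate_scan(ph, geom)
    return ph, pset


class TestDegenerateMotion:
    def test_dynamic_loss_reduces_to_static_with_zero_motion(self):
        """With zero weights and zero control points the dynamic projection
        loss equals the static projection loss on the same batch, exactly."""
        from tomoinr import training as T
        from tomoinr.bspline import MotionBasisSet
        from tomoinr.fields import SpatialINR, TemporalINR
        from tomoinr.projector import ProjectorConfig, project_single_volume_op

        ph, pset = _tiny_problem()
        grid = ph.grid
        rng = np.random.default_rng(0)
        spatial = SpatialINR(grid, rng, dtype=np.float64)
        temporal = TemporalINR(pset.n_frames, 3, 2, rng, dtype=np.float64)
        mbcs = MotionBasisSet(2, (4, 6, 8), dtype=np.float64)
        # zero the temporal MLPs so every weight is exactly zero
        for mlp in temporal.mlps:
            for W, b in zip(mlp.weights, mlp.biases):
                W.data[:] = 0.0
                b.data[:] = 0.0
        ctx = T._ScaleContext("t", grid, pset, spatial, mbcs, grid, np.float64,
                              ProjectorConfig())
        batch = np.arange(8)
        pred_dyn, _ = T._dynamic_forward(spatial, temporal, mbcs, ctx, batch)
        vol = T._render_reference(spatial, ctx)
        pred_static = project_single_volume_op(vol, grid, pset.geometry, batch)
        dyn = float(T.loss_prj_static(pred_dyn, ctx.targets[batch]).data)
        sta = float(T.loss_prj_static(pred_static, ctx.targets[batch]).data)
        assert dyn == sta


class TestGradients:
    def test_control_point_gradient_matches_finite_difference(self):
        from tomoinr import training as T
        from tomoinr.bspline import MotionBasisSet, mbc_orthonormality_loss
        from tomoinr.fields import SpatialINR, TemporalINR
        from tomoinr.projector import ProjectorConfig

        ph, pset = _tiny_problem(seed=5)
        grid = ph.grid
        rng = np.random.default_rng(1)
        spatial = SpatialINR(grid, rng, dtype=np.float64)
        spatial.encoder.tables.data[:] = rng.uniform(-0.01, 0.01, spatial.encoder.tables.shape)
        temporal = TemporalINR(pset.n_frames, 3, 2, rng, dtype=np.float64)
        mbcs = MotionBasisSet(2, (4, 6, 8), dtype=np.float64)
        for g in mbcs.levels:
            g.controls.data[:] = 0.01 * rng.standard_normal(g.controls.data.shape)
        ctx = T._ScaleContext("t", grid, pset, spatial, mbcs, grid, np.float64,
                              ProjectorConfig())
        batch = np.arange(6)

        def full_loss():
            pred, mbc_grid = T._dynamic_forward(spatial, temporal, mbcs, ctx, batch)
            return T.loss_prj_static(pred, ctx.targets[batch]) + mbc_orthonormality_loss(
                mbc_grid, 1.0
            )

        loss = full_loss()
        loss.backward()
        ctrl = mbcs.levels[0].controls
        analytic = ctrl.grad.copy()
        eps = 1e-5
        for idx in [(0, 1, 2), (1, 3, 0)]:
            keep = ctrl.data[idx]
            ctrl.data[idx] = keep + eps
            up = float(full_loss().data)
            ctrl.data[idx] = keep - eps
            dn = float(full_loss().data)
            ctrl.data[idx] = keep
            fd = (up - dn) / (2 * eps)
            assert abs(analytic[idx] - fd) <= 1e-3 * max(abs(fd), 1e-6)


@pytest.fixture(scope="module")
def tiny_run():
    ph, pset = _tiny_problem(seed=7)
    cfg = TrainingConfig(
        recon_shape=(32, 32), recon_spacing=(6.0, 6.0),
        dtype="float32", epoch_scale=0.01, seed=2,
        controls_per_axis=(4, 6, 8),
    )
    return ph, pset, cfg, run_reconstruction(pset, cfg)


class TestRunReconstruction:

    def test_same_seed_runs_are_bit_identical(self, tiny_run):
        ph, pset, cfg, state = tiny_run
        again = run_reconstruction(pset, cfg)
        a = [(h["total"], h["fidelity"]) for h in state.loss_history]
        b = [(h["total"], h["fidelity"]) for h in again.loss_history]
        assert a == b

    def test_all_five_stages_executed(self, tiny_run):
        _, _, _, state = tiny_run
        stages = {h["stage"] for h in state.loss_history}
        assert {"I.1", "I.2", "II.L1", "II.L2", "II.L3", "II.joint", "III",
                "IV.1", "IV.2", "V"} <= stages

    def test_render_frame_is_pure(self, tiny_run):
        _, _, _, state = tiny_run
        params_before = {k: p.data.copy() for k, p in state.parameters().items()}
        for t in range(0, 24, 6):
            state.render_frame(t)
        for k, p in state.parameters().items():
            assert np.array_equal(p.data, params_before[k])

    def test_dvf_continuous_in_fractional_time(self, tiny_run):
        _, _, _, state = tiny_run
        d0 = state.dvf(10.0)
        deltas = []
        for eps in (0.5, 0.1, 0.02):
            deltas.append(np.abs(state.dvf(10.0 + eps) - d0).max())
        assert deltas[0] >= deltas[1] >= deltas[2]
        # roughly linear shrinkage => continuous at t (no jumps)
        assert deltas[2] <= 0.1 * deltas[0] + 1e-9

    def test_untrained_state_renders_reference_everywhere(self):
        from tomoinr.bspline import MotionBasisSet
        from tomoinr.fields import SpatialINR, TemporalINR
        from tomoinr.training import ReconstructionState

        ph, pset = _tiny_problem(seed=9)
        grid = ph.grid
        rng = np.random.default_rng(0)
        spatial = SpatialINR(grid, rng)
        temporal = TemporalINR(pset.n_frames, 3, 2, rng)
        for mlp in temporal.mlps:
            for W, b in zip(mlp.weights, mlp.biases):
                W.data[:] = 0.0
                b.data[:] = 0.0
        state = ReconstructionState(
            spatial=spatial, temporal=temporal, mbcs=MotionBasisSet(2, (4, 6, 8)),
            config=TrainingConfig(recon_shape=(32, 32), recon_spacing=(6.0, 6.0)),
            geometry=pset.geometry, grid_low=grid, grid_high=grid, fov_grid=grid,
        )
        ref = state.reference(grid).values
        for t in (0, 12, 23):
            vol, dvf = state.render_frame(t, grid)
            assert np.all(dvf == 0)
            assert np.array_equal(vol.values, ref)
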