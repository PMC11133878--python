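"""Self-contained desk-scale experiments: simulate a breathing scenario,
run the full five-stage reconstruction, and score it against the exact
phantom truth.

These are the package's reference experiments (used by the test suite and
the results script).  Study conditions follow the simulated-scan protocol
-- a 60 s, 360-degree scan of a thorax phantom with a 30 mm tumor --
executed at desk scale: a 96 x 96 flatland grid at 2 mm, 96 frames, and a
proportionally shrunk training schedule.
"""

from __future__ import annotations

import numpy as np

from .metrics import evaluate_dynamic
from .phantom import (
    make_motion_trace,
    make_scan_geometry,
    make_thorax_phantom,
    simulate_scan,
)
from .training import TrainingConfig, run_reconstruction

__all__ = ["scenario_analog", "DESK_SCALE"]

#: desk-scale study conditions for full-pipeline runs
DESK_SCALE = dict(
    grid_shape=(96, 96),
    spacing=(2.0, 2.0),
    n_frames=96,
    duration_s=60.0,
    arc_deg=360.0,
    n_u=128,
    du_mm=2.5,
    tumor_diameter_mm=30.0,
    epoch_scale=0.1,
)


def scenario_analog(
    scenario: str,
    seed: int,
    moving_region: str = "lungs",
    amplitude_mm: float = 13.0,
    epoch_scale: float | None = None,
    lambda_tv: float | None = None,
    compute_ssim: bool = False,
    **scale_overrides,
):
    """Simulate + reconstruct + evaluate one breathing scenario.

    Returns ``(report, si_solved, si_true, state, phantom)``: the metric
    summary, the solved and programmed SI tumor trajectories (mm), and the
    underlying reconstruction state and phantom for further inspection.
    ``scale_overrides`` replace individual :data:`DESK_SCALE` entries
    (e.g. a smaller grid for cheap robustness checks).
    """
    ds = {**DESK_SCALE, **scale_overrides}
    n_frames = ds["n_frames"]
    trace = make_motion_trace(
        scenario, ds["duration_s"], n_frames / ds["duration_s"],
        seed=seed, amplitude=amplitude_mm,
    )
    phantom = make_thorax_phantom(
        ds["grid_shape"], ds["spacing"], tumor_diameter=ds["tumor_diameter_mm"],
        seed=seed, trace=trace, moving_region=moving_region,
    )
    geometry = make_scan_geometry(
        n_frames, duration=ds["duration_s"], arc_deg=ds["arc_deg"],
        ndim=2, n_u=ds["n_u"], du=ds["du_mm"],
    )
    pset = simulate_scan(phantom, geometry)
    if lambda_tv is None:
        # published per-study TV weights: 4e-4 for the digital-phantom
        # regime, 1e-4 for the physical thorax-phantom regime
        lambda_tv = 1e-4 if moving_region == "tumor" else 4e-4
    config = TrainingConfig(
        recon_shape=ds["grid_shape"], recon_spacing=ds["spacing"],
        dtype="float32", lambda_tv=lambda_tv,
        epoch_scale=ds["epoch_scale"] if epoch_scale is None else epoch_scale,
        seed=seed + 1,
    )
    state = run_reconstruction(pset, config)
    report, si_solved, si_true = evaluate_dynamic(
        state, phantom, compute_ssim=compute_ssim
    )
    return report, si_solved, si_true, state, phantom
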