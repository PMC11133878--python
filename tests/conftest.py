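"""Shared fixtures.

The expensive five-stage reconstructions are session-scoped so that the
acceptance tests and the parameter-recovery tests share a single run per
scenario.  Desk-scale study conditions: a 96 x 96 flatland thorax phantom
(2 mm pixels), a 60 s, 360-degree scan sampled at 96 frames, and the full
published stage schedule shrunk with epoch_scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from tomoinr.geometry import VolumeGrid, Volume
from tomoinr.experiments import scenario_analog
from tomoinr.phantom import make_scan_geometry


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def flat_geometry():
    return make_scan_geometry(48, duration=60.0, ndim=2, n_u=64, du=5.0)


@pytest.fixture()
def disk_volume():
    grid = VolumeGrid((96, 96), (2.0, 2.0))
    pts = grid.voxel_centers()
    vals = (np.linalg.norm(pts, axis=1) <= 60.0).astype(np.float64) * 0.02
    return Volume(grid, vals.reshape(grid.shape))


@pytest.fixture(scope="session")
def x1_run():
    """Quasi-periodic scenario: shared by image/motion accuracy tests."""
    return scenario_analog("X1", seed=11)


@pytest.fixture(scope="session")
def x5_run():
    """Single-breathing-cycle scenario (hardest for phase sorting)."""
    return scenario_analog("X5", seed=13)


@pytest.fixture(scope="session")
def cirs_run():
    """Physical-phantom analog: programmed tumor-only motion, 25 mm SI;
    half schedule (which this localized-motion case also prefers)."""
    return scenario_analog(
        "X1", seed=17, moving_region="tumor", amplitude_mm=25.0, epoch_scale=0.05
    )
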