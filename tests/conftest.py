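"""Shared fixtures: default hardware, a generic two-bead state, and a short
noiseless tracked recording reused across tracker tests (tracking is the
slow part, so it is session-scoped)."""
from __future__ import annotations

import numpy as np
import pytest

import magmicro as mg


@pytest.fixture(scope="session")
def spec() -> mg.MagnetSpec:
    return mg.MagnetSpec()


@pytest.fixture(scope="session")
def array() -> mg.SensorArray:
    return mg.make_grid_array()


@pytest.fixture(scope="session")
def generic_state() -> mg.PhysicalState:
    """A non-symmetric two-bead state with oblique moments and a disturbance."""
    u1 = np.array([0.2, 0.5, 0.84])
    u2 = np.array([-0.3, 0.9, 0.3])
    return mg.PhysicalState(
        p1=[-0.0175, 0.002, 0.015],
        p2=[0.0175, -0.003, 0.020],
        u1=u1 / np.linalg.norm(u1),
        u2=u2 / np.linalg.norm(u2),
        d=[2e-5, -1e-5, 4.5e-5],
    )


@pytest.fixture(scope="session")
def noiseless_cfg() -> mg.SimConfig:
    return mg.SimConfig(
        duration=3.0, noise_sd=0.0, dropout=mg.DropoutConfig(rate=0.0), seed=11
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_cfg) -> mg.GroundTruth:
    return mg.gen_gait_trajectory(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_stream(noiseless_truth, noiseless_cfg, spec, array) -> mg.FieldStream:
    return mg.sense(noiseless_truth, spec, array, noiseless_cfg)


@pytest.fixture(scope="session")
def tracked_noiseless(noiseless_stream, spec, array):
    """(lengths, states) for the noiseless 3 s gait stream."""
    return mg.track_stream(noiseless_stream, spec, array)
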