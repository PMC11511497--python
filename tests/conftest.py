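"""Shared fixtures: protocols, meshes, and small simulated recordings."""

from __future__ import annotations

import numpy as np
import pytest

from eitresp.protocol import build_protocol
from eitresp.simulator import (
    FlowmeterConfig,
    ThoraxPhantom,
    breath_trace,
    disk_mesh,
    simulate_recording,
)


@pytest.fixture(scope="session")
def protocol16():
    return build_protocol(16)


@pytest.fixture(scope="session")
def mesh_default():
    return disk_mesh(8, 32)


@pytest.fixture(scope="session")
def mesh_coarse():
    return disk_mesh(4, 32)


@pytest.fixture(scope="session")
def mesh_tiny():
    return disk_mesh(2, 32)


@pytest.fixture(scope="session")
def clean_recording():
    """60 s zero-noise recording with irregular breathing (shared oracle)."""
    breath = breath_trace(
        duration_s=60.0,
        period_jitter=0.1,
        tv_jitter=0.25,
        maneuver_times=(),
        seed=11,
    )
    return simulate_recording(ThoraxPhantom(), breath, seed=11)


@pytest.fixture(scope="session")
def drifting_recording():
    """120 s recording whose flow channel carries a 0.03 Hz drift."""
    breath = breath_trace(
        duration_s=120.0,
        period_jitter=0.1,
        tv_jitter=0.25,
        maneuver_times=(),
        seed=5,
    )
    flow_cfg = FlowmeterConfig(drift_amplitude_l_per_s=0.05, drift_hz=0.03)
    return simulate_recording(ThoraxPhantom(), breath, flow_cfg=flow_cfg, seed=5)


@pytest.fixture(scope="session")
def static_recording():
    """Short recording with no conductivity modulation (static medium)."""
    breath = breath_trace(duration_s=3.0, maneuver_times=(), seed=2)
    phantom = ThoraxPhantom(slope_s_per_l=0.0)
    return simulate_recording(phantom, breath, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
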