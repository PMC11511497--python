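"""End-to-end device emulation: breathing phantom -> packed raw stream.

For every frame the lung conductivity is frozen at the volume of the frame
midpoint, all 208 differential voltages are solved with the FEM model,
converted to amplified carrier bursts, quantized and packed into the raw
byte dialect.  A matching flowmeter trace and the full generator ground
truth are returned so that every downstream stage can be tested against
exact values.

The carrier generator is free-running: the phase of burst m of frame f is
``2 pi f0 t(f, m) + phi0`` with ``t(f, m) = f / frame_rate + m * (settle +
burst)``.  Because the carrier completes an integer number of cycles per
frame period at the default rates, each measurement slot sees a fixed
carrier phase from frame to frame, as the real hardware does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..protocol import ProtocolSpec, build_protocol, pack_stream
from .chain import SignalChainConfig, synth_bursts
from .flowmeter import FlowmeterConfig, synth_flow
from .forward import DEFAULT_THICKNESS, ForwardModel
from .mesh import Mesh2D, disk_mesh
from .phantom import ThoraxPhantom
from .waveform import BreathTrace

__all__ = ["SimulatedRecording", "simulate_recording"]


@dataclass(frozen=True)
class SimulatedRecording:
    """Raw stream, flow trace, and generator ground truth."""

    raw_bytes: bytes = field(repr=False)
    flow: np.ndarray = field(repr=False)
    breath: BreathTrace
    protocol: ProtocolSpec
    chain: SignalChainConfig
    flowmeter: FlowmeterConfig
    frame_times: np.ndarray
    frame_volumes: np.ndarray
    true_rms_voltages: np.ndarray  # (F, 208) at the INA input
    clipped_bursts: int
    seed: int | None

    @property
    def n_frames(self) -> int:
        return self.frame_times.shape[0]

    def ground_truth(self) -> dict:
        """JSON-serializable ground-truth record."""
        return {
            "seed": self.seed,
            "n_frames": self.n_frames,
            "frame_times_s": self.frame_times.tolist(),
            "frame_volumes_l": self.frame_volumes.tolist(),
            "breath_peak_times_s": self.breath.peak_times.tolist(),
            "breath_valley_times_s": self.breath.valley_times.tolist(),
            "tidal_volumes_l": self.breath.tidal_volumes.tolist(),
            "maneuver_times_s": list(self.breath.maneuver_times),
            "clipped_bursts": self.clipped_bursts,
        }


def simulate_recording(
    phantom: ThoraxPhantom,
    breath: BreathTrace,
    protocol: ProtocolSpec | None = None,
    chain_cfg: SignalChainConfig | None = None,
    flow_cfg: FlowmeterConfig | None = None,
    mesh: Mesh2D | None = None,
    thickness: float = DEFAULT_THICKNESS,
    seed: int | None = None,
) -> SimulatedRecording:
    """Simulate one recording session on the breathing phantom."""
    protocol = protocol or build_protocol(16)
    chain_cfg = chain_cfg or SignalChainConfig()
    flow_cfg = flow_cfg or FlowmeterConfig()
    mesh = mesh if mesh is not None else disk_mesh()
    rng = np.random.default_rng(seed)

    n_frames = int(breath.time.shape[0] / breath.fs * chain_cfg.frame_rate_hz)
    if n_frames < 2:
        raise ValueError("recording must span at least 2 frames")
    phantom.check_excursion(float(breath.volume.max()))

    frame_times = np.arange(n_frames) / chain_cfg.frame_rate_hz
    frame_volumes = breath.volume_at(frame_times + 0.5 / chain_cfg.frame_rate_hz)

    n_meas = protocol.n_measurements
    rms = np.empty((n_frames, n_meas))
    for f in range(n_frames):
        sigma = phantom.element_sigma(mesh, float(frame_volumes[f]))
        model = ForwardModel(mesh, sigma, thickness=thickness)
        rms[f] = model.solve_protocol(protocol, chain_cfg.current_rms_a).ravel()

    # free-running carrier phase per burst
    m_idx = np.arange(n_meas)
    burst_step = chain_cfg.settle_s + chain_cfg.burst_duration_s
    t_burst = frame_times[:, None] + m_idx[None, :] * burst_step
    phi0 = rng.uniform(0, 2 * np.pi)
    phases = (2 * np.pi * chain_cfg.carrier_hz * t_burst + phi0) % (2 * np.pi)

    amps = np.sqrt(2.0) * rms  # RMS -> peak carrier amplitude
    codes, clipped = synth_bursts(amps, phases, chain_cfg, rng=rng)

    slots = np.tile(m_idx % protocol.meas_per_pattern, n_frames)
    raw = pack_stream(slots, codes.reshape(-1, chain_cfg.samples_per_burst))

    flow = synth_flow(breath, flow_cfg, rng=rng)

    return SimulatedRecording(
        raw_bytes=raw,
        flow=flow,
        breath=breath,
        protocol=protocol,
        chain=chain_cfg,
        flowmeter=flow_cfg,
        frame_times=frame_times,
        frame_volumes=frame_volumes,
        true_rms_voltages=rms,
        clipped_bursts=int(clipped.sum()),
        seed=seed,
    )
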