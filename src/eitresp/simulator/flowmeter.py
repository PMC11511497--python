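"""Flowmeter channel model: gain, anti-alias low-pass, drift and noise.

Mirrors the acquisition settings of the reference transducer: 200 S/s,
second-order low-pass at 66.5 Hz with quality factor 0.5, DC-coupled.  A
slow sinusoidal drift (below 0.1 Hz, caused by sensor orientation changes)
and white noise can be added; a scale error models an uncalibrated channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .waveform import BreathTrace

__all__ = ["FlowmeterConfig", "synth_flow"]


class FlowmeterError(ValueError):
    pass


@dataclass(frozen=True)
class FlowmeterConfig:
    sample_rate_hz: float = 200.0
    gain: float = 5000.0
    lowpass_hz: float = 66.5
    quality_factor: float = 0.5
    compensation_l_per_s: float = 0.0
    drift_amplitude_l_per_s: float = 0.0
    drift_hz: float = 0.05
    noise_rms_l_per_s: float = 0.0
    scale_error: float = 1.0

    def __post_init__(self):
        if not 0 <= self.drift_hz < 0.1:
            raise FlowmeterError(
                f"drift frequency must lie in [0, 0.1) Hz, got {self.drift_hz}"
            )


def _lowpass_ba(cfg: FlowmeterConfig) -> tuple[np.ndarray, np.ndarray]:
    # analog biquad w0^2 / (s^2 + w0/Q s + w0^2), bilinear-transformed
    w0 = 2 * np.pi * cfg.lowpass_hz
    b, a = scipy.signal.bilinear(
        [w0**2], [1.0, w0 / cfg.quality_factor, w0**2], fs=cfg.sample_rate_hz
    )
    return b, a


def synth_flow(
    breath: BreathTrace,
    cfg: FlowmeterConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Recorded flow samples (L/s) for a breathing waveform.

    The true flow must already be sampled at the flowmeter rate.  Drift and
    noise are added before the causal hardware low-pass; the scale error
    divides the output (recovered later by syringe calibration).
    """
    if abs(breath.fs - cfg.sample_rate_hz) > 1e-9:
        raise FlowmeterError(
            f"breath trace sampled at {breath.fs} S/s, flowmeter at {cfg.sample_rate_hz}"
        )
    if rng is None:
        rng = np.random.default_rng()
    flow = breath.flow + cfg.compensation_l_per_s
    if cfg.drift_amplitude_l_per_s > 0:
        phase = rng.uniform(0, 2 * np.pi)
        flow = flow + cfg.drift_amplitude_l_per_s * np.sin(
            2 * np.pi * cfg.drift_hz * breath.time + phase
        )
    if cfg.noise_rms_l_per_s > 0:
        flow = flow + rng.normal(0, cfg.noise_rms_l_per_s, flow.shape)
    b, a = _lowpass_ba(cfg)
    flow = scipy.signal.lfilter(b, a, flow)
    return flow / cfg.scale_error
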