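"""Analog signal-chain model: drive synthesis constants, INA gain, input
filter, ADC quantization, and burst sampling.

The chain is: 8-bit cosine generator (1.65 V amplitude around a 1.65 V
offset), differential attenuator (220/5000), transconductance current
source set to 1 mA RMS at 50 kHz, instrumentation amplifier (gain set by
two 250-ohm resistors in series), 2.5 V output offset, and a 12-bit 5 V ADC
sampling 64-sample bursts at 350 kS/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignalChainConfig", "signal_chain_constants", "synth_burst"]


@dataclass(frozen=True)
class SignalChainConfig:
    carrier_hz: float = 50e3
    current_rms_a: float = 1e-3
    dac_amplitude_v: float = 1.65
    v_ref: float = 1.65
    atten_num_ohm: float = 220.0
    atten_den_ohm: float = 5000.0
    gain_resistor_ohm: float = 2 * 250.0
    hp_r1_ohm: float = 1e3
    hp_c1_f: float = 1e-6
    hp_r2_ohm: float = 1e3
    hp_c2_f: float = 1e-6
    adc_ref_v: float = 5.0
    adc_bits: int = 12
    output_offset_v: float = 2.5
    sample_rate_hz: float = 350e3
    samples_per_burst: int = 64
    settle_s: float = 2e-3
    frame_rate_hz: float = 2.0
    noise_rms_v: float = 0.0

    @property
    def gain(self) -> float:
        """INA gain 1 + 50 kOhm / R_G."""
        return 1.0 + 50e3 / self.gain_resistor_ohm

    @property
    def input_cutoff_hz(self) -> float:
        """Second-order passive high-pass cutoff 1 / (2 pi sqrt(R1 C1 R2 C2))."""
        return 1.0 / (
            2
            * np.pi
            * np.sqrt(self.hp_r1_ohm * self.hp_c1_f * self.hp_r2_ohm * self.hp_c2_f)
        )

    @property
    def adc_resolution_v(self) -> float:
        """Quantization step: reference / 2^bits."""
        return self.adc_ref_v / 2**self.adc_bits

    @property
    def control_amplitude_v(self) -> float:
        """Peak amplitude of the attenuated control signal."""
        return self.dac_amplitude_v * self.atten_num_ohm / self.atten_den_ohm

    @property
    def burst_duration_s(self) -> float:
        return self.samples_per_burst / self.sample_rate_hz

    @property
    def adc_code_max(self) -> int:
        return 2**self.adc_bits - 1


def signal_chain_constants(cfg: SignalChainConfig) -> dict:
    """Derived analog constants of the chain."""
    return {
        "gain": cfg.gain,
        "input_cutoff_hz": cfg.input_cutoff_hz,
        "adc_resolution_v": cfg.adc_resolution_v,
        "adc_resolution_mv_per_bit": 1e3 * cfg.adc_resolution_v,
        "control_amplitude_v": cfg.control_amplitude_v,
        "burst_duration_s": cfg.burst_duration_s,
    }


def synth_burst(
    v_amp: float,
    cfg: SignalChainConfig,
    rng: np.random.Generator | None = None,
    phase: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Sample one amplified carrier burst as ADC codes.

    ``v_amp`` is the peak differential amplitude at the INA input (V).  The
    burst is ``gain * v_amp * sin(2 pi f0 t + phase) + offset`` plus optional
    Gaussian noise, floor-quantized at the ADC step.  If ``phase`` is None a
    uniform random phase is drawn (the free-running generator makes bursts
    non-phase-sensitive).  Returns (codes, clipped): ``clipped`` is True when
    any sample left the 0..full-scale range and was pinned.
    """
    if rng is None:
        rng = np.random.default_rng()
    if phase is None:
        phase = rng.uniform(0, 2 * np.pi)
    j = np.arange(cfg.samples_per_burst)
    v = (
        cfg.gain * v_amp * np.sin(2 * np.pi * cfg.carrier_hz / cfg.sample_rate_hz * j + phase)
        + cfg.output_offset_v
    )
    if cfg.noise_rms_v > 0:
        v = v + rng.normal(0, cfg.noise_rms_v, v.shape)
    codes = np.floor(v / cfg.adc_resolution_v).astype(np.int64)
    clipped = bool((codes < 0).any() or (codes > cfg.adc_code_max).any())
    codes = np.clip(codes, 0, cfg.adc_code_max).astype(np.uint16)
    return codes, clipped


def synth_bursts(
    v_amps: np.ndarray,
    phases: np.ndarray,
    cfg: SignalChainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized form of :func:`synth_burst` for arrays of bursts.

    ``v_amps`` and ``phases`` share a leading shape; output codes gain a
    trailing axis of ``samples_per_burst``.  Returns (codes, clipped mask).
    """
    v_amps = np.asarray(v_amps, dtype=float)
    phases = np.asarray(phases, dtype=float)
    j = np.arange(cfg.samples_per_burst)
    v = (
        cfg.gain
        * v_amps[..., None]
        * np.sin(
            2 * np.pi * cfg.carrier_hz / cfg.sample_rate_hz * j + phases[..., None]
        )
        + cfg.output_offset_v
    )
    if cfg.noise_rms_v > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = v + rng.normal(0, cfg.noise_rms_v, v.shape)
    codes = np.floor(v / cfg.adc_resolution_v).astype(np.int64)
    clipped = (codes < 0).any(axis=-1) | (codes > cfg.adc_code_max).any(axis=-1)
    codes = np.clip(codes, 0, cfg.adc_code_max).astype(np.uint16)
    return codes, clipped
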