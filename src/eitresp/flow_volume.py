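"""Flow calibration, volume integration and sub-0.1 Hz drift removal.

Volume is the cumulative trapezoidal integral of calibrated flow between
p1 and p2, the midpoints of the first and last valley/peak index pairs of
the flow signal (chosen so the volume signal is not vertically shifted).
Slow drift accumulated by the integral is removed with a zero-phase
high-pass at 0.1 Hz applied to the volume signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.signal

__all__ = [
    "FlowVolumeError",
    "FlowRecord",
    "VolumeRecord",
    "integration_bounds",
    "integrate_volume",
    "remove_drift",
    "calibrate_flow",
]


class FlowVolumeError(ValueError):
    pass


@dataclass(frozen=True)
class FlowRecord:
    """Uniformly sampled flow (L/s) with the calibration scale applied."""

    samples: np.ndarray = field(repr=False)
    fs: float = 200.0
    scale: float = 1.0
    source: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise FlowVolumeError("flow record contains non-finite samples")

    def calibrated(self, scale: float) -> "FlowRecord":
        return FlowRecord(
            samples=self.samples * scale, fs=self.fs,
            scale=self.scale * scale, source=self.source,
        )


@dataclass(frozen=True)
class VolumeRecord:
    """Cumulative volume (L) defined on the sample range [p1, p2]."""

    volume: np.ndarray = field(repr=False)
    p1: int
    p2: int
    fs: float = 200.0
    drift_filtered: bool = False

    @property
    def time(self) -> np.ndarray:
        return (self.p1 + np.arange(self.volume.shape[0])) / self.fs


def integration_bounds(
    valley_indices, peak_indices
) -> tuple[int, int]:
    """Midpoint bounds (p1, p2) from flow valley/peak indices.

    p1 is the midpoint of the first valley and first peak, p2 of the last
    valley and last peak (fractional midpoints round down).  The first and
    last valleys must precede their paired peaks.
    """
    valleys = np.asarray(valley_indices)
    peaks = np.asarray(peak_indices)
    if valleys.size == 0 or peaks.size == 0:
        raise FlowVolumeError("need at least one valley and one peak")
    if valleys[0] >= peaks[0]:
        raise FlowVolumeError(
            f"first valley {valleys[0]} does not precede first peak {peaks[0]}"
        )
    if valleys[-1] >= peaks[-1]:
        raise FlowVolumeError(
            f"last valley {valleys[-1]} does not precede last peak {peaks[-1]}"
        )
    p1 = int(valleys[0] + peaks[0]) // 2
    p2 = int(valleys[-1] + peaks[-1]) // 2
    if p1 >= p2:
        raise FlowVolumeError(f"degenerate bounds p1={p1} >= p2={p2}")
    return p1, p2


def integrate_volume(flow: FlowRecord, p1: int, p2: int) -> VolumeRecord:
    """Cumulative trapezoidal volume over [p1, p2], zero at p1."""
    n = flow.samples.shape[0]
    if not 0 <= p1 < p2 < n:
        raise FlowVolumeError(f"bounds ({p1}, {p2}) outside record of length {n}")
    vol = scipy.integrate.cumulative_trapezoid(
        flow.samples[p1 : p2 + 1], dx=1.0 / flow.fs, initial=0.0
    )
    return VolumeRecord(volume=vol, p1=p1, p2=p2, fs=flow.fs)


def remove_drift(
    record: VolumeRecord, cutoff_hz: float = 0.1, order: int = 2
) -> VolumeRecord:
    """Zero-phase Butterworth high-pass suppressing the 0-0.1 Hz band."""
    n = record.volume.shape[0]
    if n / record.fs <= 10.0:
        raise FlowVolumeError("drift removal needs more than 10 s of signal")
    b, a = scipy.signal.butter(order, cutoff_hz, btype="highpass", fs=record.fs)
    filtered = scipy.signal.filtfilt(b, a, record.volume)
    return VolumeRecord(
        volume=filtered, p1=record.p1, p2=record.p2, fs=record.fs,
        drift_filtered=True,
    )


def calibrate_flow(
    raw_samples: np.ndarray,
    syringe_strokes,
    syringe_volume_l: float,
    fs: float = 200.0,
) -> float:
    """Scale factor making the mean integrated stroke equal the syringe volume.

    ``syringe_strokes`` is a list of (start, end) sample index pairs, one
    per stroke of the calibration syringe.
    """
    raw = np.asarray(raw_samples, dtype=float)
    strokes = list(syringe_strokes)
    if not strokes:
        raise FlowVolumeError("no syringe strokes identified")
    vols = []
    for start, end in strokes:
        seg = raw[start:end]
        vols.append(abs(np.trapezoid(seg, dx=1.0 / fs)))
    mean_vol = float(np.mean(vols))
    if mean_vol <= 0:
        raise FlowVolumeError("syringe strokes integrate to zero volume")
    return syringe_volume_l / mean_vol
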