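"""Breathing volume/flow waveform generator with ground-truth annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BreathTrace", "breath_trace"]


@dataclass(frozen=True)
class BreathTrace:
    """Ground-truth respiratory waveform.

    ``volume`` (L) is the inhaled volume above end-expiration; ``flow`` is
    its numerical time-derivative (L/s).  Peak/valley times and per-breath
    tidal volumes are the generator's exact annotations, used as the oracle
    in recovery tests.
    """

    time: np.ndarray
    volume: np.ndarray
    flow: np.ndarray
    fs: float
    peak_times: np.ndarray
    valley_times: np.ndarray
    tidal_volumes: np.ndarray
    maneuver_times: tuple[float, ...] = ()

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0]

    @property
    def n_breaths(self) -> int:
        return self.peak_times.shape[0]

    def volume_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.volume)


def breath_trace(
    duration_s: float = 300.0,
    fs: float = 200.0,
    mean_period_s: float = 3.4,
    period_jitter: float = 0.05,
    tv_mean_l: float = 0.8,
    tv_jitter: float = 0.1,
    maneuver_times: tuple[float, ...] = (180.0, 250.0),
    maneuver_gain: float = 2.5,
    seed: int | None = None,
) -> BreathTrace:
    """Piecewise raised-cosine breathing: one smooth cycle per breath.

    Each cycle i lasts ``T_i = mean_period * (1 + jitter)`` and inhales
    ``TV_i`` litres along ``TV_i * (1 - cos(2 pi t / T_i)) / 2``, so volume
    returns to the end-expiration baseline at every cycle boundary.  Cycles
    whose start falls within half a period of a maneuver time get their
    amplitude scaled by ``maneuver_gain`` (forced inspiration/expiration).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    volume = np.zeros_like(t)
    peaks, valleys, tvs, used_maneuvers = [], [], [], []
    t0 = 0.0
    while t0 < duration_s:
        T = mean_period_s * (1 + period_jitter * rng.uniform(-1, 1))
        tv = tv_mean_l * (1 + tv_jitter * rng.uniform(-1, 1))
        for mt in maneuver_times:
            if abs(t0 + T / 2 - mt) < T / 2 and mt not in used_maneuvers:
                tv *= maneuver_gain
                used_maneuvers.append(mt)
                break
        sel = (t >= t0) & (t < t0 + T)
        volume[sel] = 0.5 * tv * (1 - np.cos(2 * np.pi * (t[sel] - t0) / T))
        if t0 + T <= duration_s:  # only whole cycles are annotated
            valleys.append(t0)
            peaks.append(t0 + T / 2)
            tvs.append(tv)
        t0 += T
    flow = np.gradient(volume, 1.0 / fs)
    return BreathTrace(
        time=t,
        volume=volume,
        flow=flow,
        fs=fs,
        peak_times=np.array(peaks),
        valley_times=np.array(valleys),
        tidal_volumes=np.array(tvs),
        maneuver_times=tuple(used_maneuvers),
    )
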