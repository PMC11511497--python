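"""Breath detection, signal alignment and detection scoring.

Breaths are delimited by alternating peaks and valleys found on a
respiratory signal (volume, a voltage-matrix row, or a pixel series).  A
breath is the cycle from one peak to the next; per-breath durations come
from differencing the peak time vector.  Voltage series at 2 Hz are
linearly interpolated by a factor of 100 to the 200 Hz flowmeter clock and
aligned by cross-correlation before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = [
    "BreathError",
    "BreathAnnotation",
    "MatchResult",
    "AlignResult",
    "detect_extrema",
    "upsample_voltage",
    "align_by_xcorr",
    "instantaneous_rate",
    "truncate_pair",
    "match_breaths",
    "detection_metrics",
]


class BreathError(ValueError):
    pass


@dataclass(frozen=True)
class BreathAnnotation:
    """Alternating peak/valley sample indices on one signal."""

    peaks: np.ndarray
    valleys: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "peaks", np.asarray(self.peaks, dtype=np.int64))
        object.__setattr__(self, "valleys", np.asarray(self.valleys, dtype=np.int64))
        merged = np.concatenate(
            [
                np.column_stack([self.peaks, np.ones_like(self.peaks)]),
                np.column_stack([self.valleys, np.zeros_like(self.valleys)]),
            ]
        )
        merged = merged[np.argsort(merged[:, 0], kind="stable")]
        if merged.shape[0] > 1:
            if (np.diff(merged[:, 0]) <= 0).any():
                raise BreathError("extrema indices must be strictly increasing")
            if (np.diff(merged[:, 1]) == 0).any():
                raise BreathError("peaks and valleys must strictly alternate")

    @property
    def peak_times(self) -> np.ndarray:
        return self.peaks / self.fs

    @property
    def valley_times(self) -> np.ndarray:
        return self.valleys / self.fs

    @property
    def n_breaths(self) -> int:
        return max(0, self.peaks.shape[0] - 1)

    @property
    def durations(self) -> np.ndarray:
        """Per-breath durations (s), peak to next peak."""
        return np.diff(self.peak_times)


def _enforce_alternation(
    signal: np.ndarray, peaks: np.ndarray, valleys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the lesser of two same-type neighbours until types alternate."""
    events = [(int(i), 1) for i in peaks] + [(int(i), 0) for i in valleys]
    events.sort()
    cleaned: list[tuple[int, int]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx = cleaned[-1][0]
            better = (signal[idx] > signal[prev_idx]) if kind == 1 else (
                signal[idx] < signal[prev_idx]
            )
            if better:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    new_peaks = np.array([i for i, k in cleaned if k == 1], dtype=np.int64)
    new_valleys = np.array([i for i, k in cleaned if k == 0], dtype=np.int64)
    return new_peaks, new_valleys


def detect_extrema(
    signal: np.ndarray,
    fs: float,
    min_prominence_frac: float = 0.2,
    min_separation_s: float = 1.0,
) -> BreathAnnotation:
    """Find alternating respiratory peaks and valleys.

    Prominence is thresholded at a fraction of the total signal range and
    same-type extrema closer than ``min_separation_s`` are suppressed.  A
    flat signal yields an empty annotation.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise BreathError("sampling rate must be positive")
    if not np.all(np.isfinite(signal)):
        raise BreathError("signal contains non-finite values")
    rng = signal.max() - signal.min()
    if rng == 0:
        empty = np.array([], dtype=np.int64)
        return BreathAnnotation(peaks=empty, valleys=empty, fs=fs)
    prominence = min_prominence_frac * rng
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = scipy.signal.find_peaks(signal, prominence=prominence, distance=distance)
    valleys, _ = scipy.signal.find_peaks(
        -signal, prominence=prominence, distance=distance
    )
    peaks, valleys = _enforce_alternation(signal, peaks, valleys)
    return BreathAnnotation(peaks=peaks, valleys=valleys, fs=fs)


def upsample_voltage(
    values: np.ndarray, fs_in: float = 2.0, factor: int = 100
) -> np.ndarray:
    """Linear interpolation onto a grid ``factor`` times finer.

    Original samples are preserved at their instants; the output spans the
    same duration with ``(n - 1) * factor + 1`` samples.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise BreathError("need at least 2 frames to interpolate")
    n = values.shape[0]
    t_in = np.arange(n) / fs_in
    t_out = np.arange((n - 1) * factor + 1) / (fs_in * factor)
    return np.interp(t_out, t_in, values)


@dataclass(frozen=True)
class AlignResult:
    lag_s: float
    lag_samples: int
    shifted: np.ndarray
    r_before: float
    r_after: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def align_by_xcorr(
    voltage: np.ndarray,
    volume: np.ndarray,
    fs: float,
    max_lag_s: float = 5.0,
    min_overlap_s: float = 10.0,
) -> AlignResult:
    """Shift the voltage series to maximize correlation with volume.

    The lag search covers +/- ``max_lag_s``; for each candidate lag the
    Pearson correlation of the mean-removed overlapping segments is
    computed and the best lag is kept, so the post-shift correlation can
    never fall below the unshifted one.  The shifted series keeps its
    length, holding edge values where the shift exposes samples.
    """
    v = np.asarray(voltage, dtype=float)
    w = np.asarray(volume, dtype=float)
    n = min(v.shape[0], w.shape[0])
    v, w = v[:n], w[:n]
    max_lag = int(round(max_lag_s * fs))
    min_overlap = int(round(min_overlap_s * fs))
    if n - max_lag < min_overlap:
        raise BreathError(
            f"only {n} samples: need {min_overlap + max_lag} for alignment"
        )
    best_lag, best_r = 0, -np.inf
    r0 = _pearson(v, w)
    for lag in range(-max_lag, max_lag + 1):
        # positive lag: voltage delayed, shift it left by lag
        if lag >= 0:
            a, b = v[lag:], w[: n - lag]
        else:
            a, b = v[: n + lag], w[-lag:]
        r = _pearson(a, b)
        if r > best_r:
            best_lag, best_r = lag, r
    if best_lag >= 0:
        shifted = np.concatenate([v[best_lag:], np.full(best_lag, v[-1])])
    else:
        shifted = np.concatenate([np.full(-best_lag, v[0]), v[:best_lag]])
    return AlignResult(
        lag_s=best_lag / fs,
        lag_samples=best_lag,
        shifted=shifted,
        r_before=r0,
        r_after=best_r,
    )


def instantaneous_rate(
    annotation: BreathAnnotation,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-breath durations (s) and rates (breaths/min)."""
    if annotation.peaks.shape[0] < 2:
        raise BreathError("need at least 2 peaks for instantaneous rate")
    durations = annotation.durations
    return durations, 60.0 / durations


def truncate_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Truncate the longer sequence to the length of the shorter one."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = min(a.shape[0], b.shape[0])
    return a[:n], b[:n]


@dataclass(frozen=True)
class MatchResult:
    """Breath-detection confusion counts and the matched peak pairs."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...] = ()


def match_breaths(
    ref: BreathAnnotation,
    test: BreathAnnotation,
    tolerance_s: float | None = None,
) -> MatchResult:
    """Greedy nearest-peak matching between reference and test annotations.

    Default tolerance is half the median reference breath duration.  Each
    peak is used at most once; unmatched test peaks are false positives,
    unmatched reference peaks false negatives.
    """
    rt = ref.peak_times
    tt = test.peak_times
    if tolerance_s is None:
        if rt.shape[0] < 2:
            raise BreathError("cannot derive tolerance from fewer than 2 ref peaks")
        tolerance_s = float(np.median(np.diff(rt))) / 2.0
    candidates = []
    for i, t_ref in enumerate(rt):
        for j, t_test in enumerate(tt):
            dt = abs(t_ref - t_test)
            if dt <= tolerance_s:
                candidates.append((dt, i, j))
    candidates.sort()
    used_ref: set[int] = set()
    used_test: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_ref or j in used_test:
            continue
        used_ref.add(i)
        used_test.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=tt.shape[0] - tp, fn=rt.shape[0] - tp, pairs=tuple(sorted(pairs))
    )


def detection_metrics(m: MatchResult) -> tuple[float, float, float]:
    """Sensitivity TP/(TP+FN), precision TP/(TP+FP) and their harmonic mean."""
    if m.tp + m.fn == 0 or m.tp + m.fp == 0:
        raise BreathError("detection metrics undefined: zero denominator")
    se = m.tp / (m.tp + m.fn)
    pr = m.tp / (m.tp + m.fp)
    if se + pr == 0:
        raise BreathError("F1 undefined: Se + Pr = 0")
    f1 = 2 * se * pr / (se + pr)
    return se, pr, f1
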