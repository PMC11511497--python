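"""Per-subject tidal-volume regression from voltage breath amplitudes.

The tidal volume of a breath is the signal rise from a valley to the
following peak.  A per-subject linear model maps voltage amplitudes to
volumes; the origin (0, 0) is appended as one ordinary observation (not a
through-origin constraint) before the least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .breaths import BreathAnnotation

__all__ = [
    "TVError",
    "TVDataset",
    "TVRegression",
    "TVEvaluation",
    "breath_amplitudes",
    "fit_tv",
    "evaluate_tv",
    "weighted_mean",
    "select_best_measurement",
]


class TVError(ValueError):
    pass


@dataclass(frozen=True)
class TVDataset:
    """Paired per-breath voltage amplitudes (V) and observed volumes (L)."""

    amplitudes: np.ndarray
    volumes: np.ndarray
    subject_id: str = ""
    measurement_id: int | None = None

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "volumes", vols)
        if amps.shape != vols.shape:
            raise TVError("amplitudes and volumes differ in length")
        if (amps < 0).any():
            raise TVError("amplitudes must be non-negative")
        if (vols <= 0).any():
            raise TVError("volumes must be positive")

    @property
    def n_breaths(self) -> int:
        return self.amplitudes.shape[0]


@dataclass(frozen=True)
class TVRegression:
    """y = intercept + slope * x, fitted with the (0, 0) anchor point."""

    intercept: float
    slope: float
    anchored: bool = True

    def predict(self, amplitudes) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(amplitudes, dtype=float)


def breath_amplitudes(
    signal: np.ndarray, annotation: BreathAnnotation
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-breath valley-to-peak amplitudes of a signal.

    Returns (amplitudes, peak indices used, skipped count); a peak without a
    preceding valley contributes to the skipped count.
    """
    signal = np.asarray(signal, dtype=float)
    amps, used = [], []
    skipped = 0
    for p in annotation.peaks:
        prev = annotation.valleys[annotation.valleys < p]
        if prev.size == 0:
            skipped += 1
            continue
        v = prev[-1]
        amps.append(signal[p] - signal[v])
        used.append(p)
    return np.asarray(amps, dtype=float), np.asarray(used, dtype=np.int64), skipped


def fit_tv(dataset: TVDataset, anchor: bool = True, through_origin: bool = False) -> TVRegression:
    """Least-squares volume-vs-amplitude line.

    With ``anchor`` (default) the point (0, 0) joins the observations as one
    extra sample; ``through_origin`` instead constrains the intercept to 0.
    """
    if dataset.n_breaths < 2:
        raise TVError("need at least 2 breaths to fit")
    x = dataset.amplitudes
    y = dataset.volumes
    if np.ptp(x) == 0:
        raise TVError("zero variance in amplitudes")
    if through_origin:
        slope = float(x @ y / (x @ x))
        return TVRegression(intercept=0.0, slope=slope, anchored=False)
    if anchor:
        x = np.concatenate([x, [0.0]])
        y = np.concatenate([y, [0.0]])
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return TVRegression(intercept=float(coef[0]), slope=float(coef[1]), anchored=anchor)


@dataclass(frozen=True)
class TVEvaluation:
    pearson_r: float
    spearman_rho: float
    rmse_l: float
    mape_pct: float
    n_breaths: int


def evaluate_tv(model: TVRegression, dataset: TVDataset) -> TVEvaluation:
    """Observed-vs-predicted agreement metrics for one subject."""
    if dataset.n_breaths < 3:
        raise TVError("correlation undefined with fewer than 3 breaths")
    obs = dataset.volumes
    pred = model.predict(dataset.amplitudes)
    err = obs - pred
    r = float(np.corrcoef(obs, pred)[0, 1])
    rho = float(scipy.stats.spearmanr(obs, pred).statistic)
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err) / obs) * 100.0)
    return TVEvaluation(
        pearson_r=r, spearman_rho=rho, rmse_l=rmse, mape_pct=mape,
        n_breaths=dataset.n_breaths,
    )


def weighted_mean(values, weights) -> float:
    """Breath-count-weighted cohort mean of a per-subject metric."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.size == 0:
        raise TVError("values and weights must be equal-length and non-empty")
    return float(np.sum(values * weights) / np.sum(weights))


def select_best_measurement(
    matrix_values: np.ndarray, volume_at_frames: np.ndarray
) -> tuple[int, np.ndarray]:
    """Row of the voltage matrix with maximal |Pearson r| against volume.

    Returns (row index, per-row correlation vector).  Rows with zero
    variance get correlation 0.
    """
    v = np.asarray(matrix_values, dtype=float)
    w = np.asarray(volume_at_frames, dtype=float)
    if v.shape[1] != w.shape[0]:
        raise TVError("frame count mismatch between matrix and volume")
    vc = v - v.mean(axis=1, keepdims=True)
    wc = w - w.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (wc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, vc @ wc / denom, 0.0)
    return int(np.argmax(np.abs(r))), r
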