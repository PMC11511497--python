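"""End-to-end analysis: raw stream + flow trace -> breaths, rates, volumes.

This is the glue the CLI (and tests) drive: decode and demodulate the
stream, integrate and de-drift the flow, annotate breaths on both signals,
align them, score detection, and fit the per-subject tidal-volume model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breaths as br
from . import flow_volume as fv
from . import preprocess as pp
from . import tv_model as tv
from .agreement import AgreementReport, bland_altman_np

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_recording"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    flow_fs: float = 200.0
    flow_scale: float = 1.0
    frame_rate_hz: float = 2.0
    adc_step_v: float = pp.DEFAULT_ADC_STEP_V
    bandpass_low_hz: float = 40e3
    bandpass_high_hz: float = 60e3
    bandpass_order: int = 1
    edge_trim: int = 8
    drift_cutoff_hz: float = 0.1
    min_prominence_frac: float = 0.2
    min_separation_s: float = 1.0
    max_lag_s: float = 5.0
    upsample_factor: int = 100
    match_tolerance_s: float | None = None


@dataclass(frozen=True)
class AnalysisResult:
    voltage_matrix: pp.VoltageMatrix
    prefix_bytes: int
    volume: fv.VolumeRecord
    volume_annotation: br.BreathAnnotation
    voltage_annotation: br.BreathAnnotation
    best_measurement: int  # 0-based row of the voltage matrix
    best_measurement_r: float
    row_correlations: np.ndarray = field(repr=False)
    alignment: br.AlignResult
    rate_comparison: AgreementReport
    match: br.MatchResult
    sensitivity: float
    precision: float
    f1: float
    tv_dataset: tv.TVDataset
    tv_regression: tv.TVRegression
    tv_evaluation: tv.TVEvaluation
    tv_agreement: AgreementReport
    log: dict

    def summary_frame(self) -> pd.DataFrame:
        """One-row summary of the headline outputs."""
        return pd.DataFrame(
            [
                {
                    "frames": self.voltage_matrix.n_frames,
                    "prefix_bytes": self.prefix_bytes,
                    "best_measurement_1based": self.best_measurement + 1,
                    "best_measurement_r": self.best_measurement_r,
                    "volume_breaths": len(self.volume_annotation.peaks),
                    "voltage_breaths": len(self.voltage_annotation.peaks),
                    "Se": self.sensitivity,
                    "Pr": self.precision,
                    "F1": self.f1,
                    "tv_slope": self.tv_regression.slope,
                    "tv_intercept": self.tv_regression.intercept,
                    "tv_r": self.tv_evaluation.pearson_r,
                    "tv_rmse_l": self.tv_evaluation.rmse_l,
                    "tv_mape_pct": self.tv_evaluation.mape_pct,
                }
            ]
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def analyze_recording(
    raw_bytes: bytes,
    flow_samples: np.ndarray,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the full comparison pipeline on one recording."""
    cfg = config or AnalysisConfig()
    log: dict = {}

    # --- demodulation -----------------------------------------------------
    decoded = _stage("decode")(pp.decode_stream)(raw_bytes)
    cube = _stage("reshape")(pp.reshape_frames)(
        decoded, adc_step_v=cfg.adc_step_v, frame_rate_hz=cfg.frame_rate_hz
    )
    matrix = _stage("demodulate")(pp.demodulate)(
        cube,
        low_hz=cfg.bandpass_low_hz,
        high_hz=cfg.bandpass_high_hz,
        order=cfg.bandpass_order,
        edge_trim=cfg.edge_trim,
    )
    log["frames_decoded"] = matrix.n_frames
    log["prefix_bytes"] = decoded.prefix_bytes

    # --- flow to volume ---------------------------------------------------
    flow = fv.FlowRecord(
        samples=np.asarray(flow_samples, dtype=float) * cfg.flow_scale,
        fs=cfg.flow_fs,
        scale=cfg.flow_scale,
    )
    flow_ann = _stage("flow extrema")(br.detect_extrema)(
        flow.samples, flow.fs, cfg.min_prominence_frac, cfg.min_separation_s
    )
    peaks, valleys = flow_ann.peaks, flow_ann.valleys
    # the bounds rule wants a valley before the first peak and before the
    # last peak; drop leading peaks / trailing valleys that violate it
    while peaks.size and valleys.size and peaks[0] < valleys[0]:
        peaks = peaks[1:]
    while peaks.size and valleys.size and valleys[-1] > peaks[-1]:
        valleys = valleys[:-1]
    p1, p2 = _stage("integration bounds")(fv.integration_bounds)(valleys, peaks)
    volume = _stage("integrate")(fv.integrate_volume)(flow, p1, p2)
    volume = _stage("drift removal")(fv.remove_drift)(volume, cfg.drift_cutoff_hz)
    vol_ann = _stage("volume extrema")(br.detect_extrema)(
        volume.volume, volume.fs, cfg.min_prominence_frac, cfg.min_separation_s
    )
    log["volume_breaths"] = int(len(vol_ann.peaks))

    # --- best-correlated measurement --------------------------------------
    frame_times = matrix.frame_times
    t1, t2 = p1 / flow.fs, p2 / flow.fs
    sel = (frame_times >= t1) & (frame_times <= t2)
    if sel.sum() < 4:
        raise PipelineError("stage 'row selection' failed: too few frames in bounds")
    vol_at_frames = np.interp(frame_times[sel], volume.time, volume.volume)
    best, row_r = _stage("row selection")(tv.select_best_measurement)(
        matrix.values[:, sel], vol_at_frames
    )
    log["best_measurement"] = best + 1

    # --- alignment and breath detection on the voltage signal -------------
    ups = _stage("upsample")(br.upsample_voltage)(
        matrix.values[best], fs_in=cfg.frame_rate_hz, factor=cfg.upsample_factor
    )
    sign = 1.0 if row_r[best] >= 0 else -1.0
    # clip the upsampled series to [p1, p2] on the common 200 Hz clock
    hi = min(p2 + 1, ups.shape[0])
    vseg = sign * ups[p1:hi]
    wseg = volume.volume[: vseg.shape[0]]
    align = _stage("alignment")(br.align_by_xcorr)(
        vseg, wseg, flow.fs, max_lag_s=cfg.max_lag_s
    )
    volt_ann = _stage("voltage extrema")(br.detect_extrema)(
        align.shifted, flow.fs, cfg.min_prominence_frac, cfg.min_separation_s
    )
    log["voltage_breaths"] = int(len(volt_ann.peaks))
    vol_ann_seg = br.BreathAnnotation(
        peaks=vol_ann.peaks[: np.searchsorted(vol_ann.peaks, wseg.shape[0])],
        valleys=vol_ann.valleys[: np.searchsorted(vol_ann.valleys, wseg.shape[0])],
        fs=volume.fs,
    )

    # --- instantaneous rate comparison ------------------------------------
    dur_vol, _ = _stage("rate (volume)")(br.instantaneous_rate)(vol_ann_seg)
    dur_volt, _ = _stage("rate (voltage)")(br.instantaneous_rate)(volt_ann)
    a, b = br.truncate_pair(dur_vol, dur_volt)
    rate_cmp = _stage("rate comparison")(bland_altman_np)(a, b)

    # --- detection scoring ------------------------------------------------
    match = _stage("matching")(br.match_breaths)(
        vol_ann_seg, volt_ann, cfg.match_tolerance_s
    )
    se, pr, f1 = _stage("detection metrics")(br.detection_metrics)(match)

    # --- tidal-volume model -----------------------------------------------
    tv_vol, tv_peaks, _ = _stage("tv (volume)")(tv.breath_amplitudes)(
        wseg, vol_ann_seg
    )
    amp_volt, amp_peaks, _ = _stage("tv (voltage)")(tv.breath_amplitudes)(
        align.shifted, volt_ann
    )
    tv_by_peak = dict(zip(tv_peaks.tolist(), tv_vol.tolist()))
    amp_by_peak = dict(zip(amp_peaks.tolist(), amp_volt.tolist()))
    obs, amps = [], []
    for i_ref, j_test in match.pairs:
        pk_ref = int(vol_ann_seg.peaks[i_ref])
        pk_test = int(volt_ann.peaks[j_test])
        if pk_ref in tv_by_peak and pk_test in amp_by_peak:
            v = tv_by_peak[pk_ref]
            x = amp_by_peak[pk_test]
            if v > 0 and x >= 0:
                obs.append(v)
                amps.append(x)
    dataset = tv.TVDataset(
        amplitudes=np.array(amps), volumes=np.array(obs), measurement_id=best
    )
    regression = _stage("tv fit")(tv.fit_tv)(dataset)
    evaluation = _stage("tv eval")(tv.evaluate_tv)(regression, dataset)
    tv_agree = _stage("tv agreement")(bland_altman_np)(
        dataset.volumes, regression.predict(dataset.amplitudes)
    )
    log["tv_breaths"] = dataset.n_breaths

    return AnalysisResult(
        voltage_matrix=matrix,
        prefix_bytes=decoded.prefix_bytes,
        volume=volume,
        volume_annotation=vol_ann_seg,
        voltage_annotation=volt_ann,
        best_measurement=best,
        best_measurement_r=float(row_r[best]),
        row_correlations=row_r,
        alignment=align,
        rate_comparison=rate_cmp,
        match=match,
        sensitivity=se,
        precision=pr,
        f1=f1,
        tv_dataset=dataset,
        tv_regression=regression,
        tv_evaluation=evaluation,
        tv_agreement=tv_agree,
        log=log,
    )
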