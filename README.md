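# eitresp

A complete, tested implementation of the computational chain of a portable
16-electrode electrical impedance tomography (EIT) respiratory monitor:

- **protocol** — the modified Sheffield adjacent stimulation/measurement
  schedule (16 patterns x 13 differential pairs = 208 combinations per
  frame), the current-multiplexer selector map, and the raw byte dialect
  (16-bit words: 4-bit measurement slot + 12-bit ADC code, 64 samples per
  measurement, high byte first).
- **simulator** — a synthetic device: 2D FEM forward solver on a symmetric
  disk/ellipse mesh, a thorax phantom whose two lung ellipses modulate
  conductivity with a breathing waveform, the analog chain (1 mA RMS 50 kHz
  drive, INA gain 101, 2.5 V offset, 12-bit 5 V ADC at 350 kS/s taking
  64-sample bursts, 2 frames/s), and a matched flowmeter channel (200 S/s,
  66.5 Hz low-pass, optional sub-0.1 Hz drift).
- **preprocess** — stream re-synchronization and decoding, 64 x 208 x F
  reshaping, zero-phase band-pass around the carrier, and peak-to-peak
  demodulation into the 208 x F voltage matrix.
- **flow_volume** — syringe calibration, trapezoidal integration between
  midpoint bounds, and zero-phase 0.1 Hz high-pass drift removal on volume.
- **breaths** — peak/valley annotation, x100 interpolation of 2 Hz series,
  cross-correlation alignment, instantaneous respiratory rate, greedy
  breath matching and Se/Pr/F1 scoring.
- **tv_model** — per-subject tidal-volume regression from valley-to-peak
  voltage amplitudes, with the (0, 0) anchor as an ordinary observation.
- **agreement** — nonparametric Bland-Altman (median, IQR,
  RPC = 1.45 x IQR) and the full comparison summary table.
- **reconstruct** — adjoint-method sensitivity matrix, one-step Tikhonov
  difference imaging on a 32 x 32 pixel grid, pixel time series and
  pixel-volume correlation maps.
- **pipeline / cli** — end-to-end orchestration and command-line tools.

## CLI

```bash
# write raw.bin, flow.csv, ground_truth.json and a manifest
eitresp simulate out/sim --seed 1 --duration 300

# full analysis: voltage matrix, volume, breath detection, TV regression,
# rate comparison and Bland-Altman tables
eitresp analyze out/sim/raw.bin out/sim/flow.csv out/analysis

# difference images against frame 0, plus a PNG preview
eitresp reconstruct out/sim/raw.bin out/recon

eitresp report out/analysis
```

Commands accept `--config <json>` to override simulator/analysis defaults
(see `AnalysisConfig`, `SignalChainConfig`, `FlowmeterConfig`,
`ThoraxPhantom`).

## Conventions worth knowing

- Electrodes are numbered 1-16 counter-clockwise, electrode 1 at angle 0.
- Odd electrodes only source current, even electrodes only sink it; the
  even member of a measurement pair is the positive amplifier terminal.
- Demodulated voltages are reported at the ADC input (after the gain of
  101); `demodulate(..., gain=101)` converts to electrode-level volts.
- The carrier/sample-rate ratio is exactly 1/7, so each 64-sample burst
  visits 7 carrier phases and peak-to-peak demodulation reads a few percent
  under the continuous swing; the effect is constant per measurement slot
  at the default timing and cancels in correlations and regressions.
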