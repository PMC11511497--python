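"""Stream decoding, reshaping, filtering and demodulation."""

import numpy as np
import pytest

from eitresp import preprocess as pp
from eitresp.protocol import pack_stream
from eitresp.simulator import SignalChainConfig


def _tone_amplitude(x, freq, fs):
    """Least-squares amplitude of one tone (independent measurement oracle)."""
    t = np.arange(len(x)) / fs
    A = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(np.hypot(*coef))


def _synthetic_stream(n_frames=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n_frames * 208
    slots = np.tile(np.arange(13), 16 * n_frames)
    samples = rng.integers(0, 4096, (n, 64)).astype(np.uint16)
    return pack_stream(slots, samples), slots, samples


class TestDecodeStream:
    def test_clean_stream_prefix_zero(self):
        raw, slots, samples = _synthetic_stream()
        d = pp.decode_stream(raw)
        assert d.prefix_bytes == 0
        assert d.n_measurements == 416
        np.testing.assert_array_equal(d.slots, slots)
        np.testing.assert_array_equal(d.samples, samples)

    def test_corrupted_prefix_resync(self):
        raw, _, _ = _synthetic_stream()
        garbage = bytes([0xFF]) * 37  # slot 15 = sync-invalid everywhere
        d = pp.decode_stream(garbage + raw)
        assert d.prefix_bytes == 37
        assert d.n_measurements == 416

    def test_all_invalid_stream_fails(self):
        with pytest.raises(pp.DecodeError):
            pp.decode_stream(bytes([0xFF]) * (2 * pp.FRAME_SAMPLES + 100))

    def test_trailing_partial_measurement_dropped(self):
        raw, _, _ = _synthetic_stream()
        with pytest.warns(UserWarning, match="trailing"):
            d = pp.decode_stream(raw + raw[:50])
        assert d.n_measurements == 416

    def test_simulator_round_trip_bit_exact(self, clean_recording):
        """decode -> repack reproduces the zero-noise stream byte for byte."""
        d = pp.decode_stream(clean_recording.raw_bytes)
        assert d.prefix_bytes == 0
        assert pack_stream(d.slots, d.samples) == clean_recording.raw_bytes


class TestReshapeFrames:
    def test_exact_multiple(self):
        raw, _, samples = _synthetic_stream(n_frames=3)
        cube = pp.reshape_frames(pp.decode_stream(raw))
        assert cube.volts.shape == (64, 208, 3)
        # ordering: sample s of measurement m of frame f
        expect = samples[208 + 5, 17] * pp.DEFAULT_ADC_STEP_V
        assert cube.volts[17, 5, 1] == pytest.approx(expect)

    def test_remainder_clipped(self):
        flat = np.zeros(pp.FRAME_SAMPLES + 500, dtype=np.uint16)
        cube = pp.reshape_frames(flat)
        assert cube.n_frames == 1

    def test_single_frame_minimum(self):
        with pytest.raises(pp.DecodeError):
            pp.reshape_frames(np.zeros(pp.FRAME_SAMPLES - 1, dtype=np.uint16))

    def test_simulator_frame_count(self, clean_recording):
        cube = pp.reshape_frames(pp.decode_stream(clean_recording.raw_bytes))
        assert cube.n_frames == clean_recording.n_frames

    def test_frame_timestamps(self):
        raw, _, _ = _synthetic_stream(n_frames=2)
        cube = pp.reshape_frames(pp.decode_stream(raw))
        np.testing.assert_allclose(cube.frame_times, [0.0, 0.5])


class TestBandpass:
    def test_constant_removed(self):
        out = pp.bandpass_measurement(np.full(64, 3.3))
        assert np.abs(out).max() < 1e-9

    def test_carrier_preserved(self):
        t = np.arange(64) / 350e3
        x = 0.8 * np.sin(2 * np.pi * 50e3 * t + 0.4)
        out = pp.bandpass_measurement(x)
        amp = _tone_amplitude(out[8:-8], 50e3, 350e3)
        assert amp == pytest.approx(0.8, rel=0.05)

    def test_interferer_attenuated(self):
        """Steady-state: a 1 kHz interferer drops by far more than 20 dB."""
        t = np.arange(4096) / 350e3
        x = (
            0.5 * np.sin(2 * np.pi * 50e3 * t)
            + 0.5 * np.sin(2 * np.pi * 1e3 * t)
            + 1.0
        )
        out = pp.bandpass_measurement(x)
        a_int = _tone_amplitude(out[256:-256], 1e3, 350e3)
        a_car = _tone_amplitude(out[256:-256], 50e3, 350e3)
        assert a_int < 0.5 / 10  # > 20 dB down
        assert a_car == pytest.approx(0.5, rel=0.05)


class TestPeakToPeak:
    def test_constant_burst_zero(self):
        cube = pp.VoltageCube(np.full((64, 208, 2), 2.5))
        mat = pp.peak_to_peak(cube)
        assert mat.values.shape == (208, 2)
        np.testing.assert_allclose(mat.values, 0.0)

    def test_matrix_nonnegative(self, clean_recording):
        mat = pp.demodulate(
            pp.reshape_frames(pp.decode_stream(clean_recording.raw_bytes))
        )
        assert (mat.values >= 0).all()
        assert mat.values.shape == (208, clean_recording.n_frames)

    def test_amplitude_recovery_vs_ground_truth(self, clean_recording):
        """Demodulated pk-pk approximates 2 * gain * amplitude."""
        cfg = clean_recording.chain
        mat = pp.demodulate(
            pp.reshape_frames(pp.decode_stream(clean_recording.raw_bytes))
        )
        truth = 2 * cfg.gain * np.sqrt(2) * np.abs(clean_recording.true_rms_voltages.T)
        ratio = mat.values / truth
        # the 1/7 carrier/sample-rate ratio leaves 7 sampled phases per
        # burst, so pk-pk reads a few percent under the continuous swing
        assert np.median(ratio) == pytest.approx(0.97, abs=0.03)
        assert ratio.max() < 1.01
        assert ratio.min() > 0.92

    def test_gain_division_option(self, clean_recording):
        cube = pp.reshape_frames(pp.decode_stream(clean_recording.raw_bytes))
        at_adc = pp.demodulate(cube)
        at_electrodes = pp.demodulate(cube, gain=101.0)
        np.testing.assert_allclose(at_electrodes.values, at_adc.values / 101.0)


class TestVoltageProfile:
    def test_u_shape_on_homogeneous_simulation(self, protocol16, mesh_default):
        """Forward-model oracle: block minima at the farthest pair."""
        from eitresp.simulator import ForwardModel
        from eitresp.simulator.chain import synth_bursts

        V = ForwardModel(mesh_default, 0.48).solve_protocol(protocol16).ravel()
        cfg = SignalChainConfig()
        # a fixed phase gives every burst the same demodulation factor, so
        # the profile ordering is exactly the forward model's
        phases = np.zeros(V.shape)
        codes, _ = synth_bursts(np.sqrt(2) * V, phases, cfg)
        cube = pp.reshape_frames(codes.reshape(-1))
        profile, minima = pp.voltage_profile(pp.demodulate(cube), 0)
        truth_minima = np.abs(V.reshape(16, 13)).argmin(axis=1) + 13 * np.arange(16)
        np.testing.assert_array_equal(minima, truth_minima)

    def test_static_profiles_identical(self, static_recording):
        mat = pp.demodulate(
            pp.reshape_frames(pp.decode_stream(static_recording.raw_bytes))
        )
        p0, _ = pp.voltage_profile(mat, 0)
        p1, _ = pp.voltage_profile(mat, mat.n_frames - 1)
        np.testing.assert_array_equal(p0, p1)

    def test_frame_out_of_range(self, static_recording):
        mat = pp.demodulate(
            pp.reshape_frames(pp.decode_stream(static_recording.raw_bytes))
        )
        with pytest.raises(IndexError):
            pp.voltage_profile(mat, mat.n_frames)

    def test_breathing_row_correlates_with_volume(self, clean_recording):
        """Recovery property: some row tracks the generating waveform."""
        rec = clean_recording
        mat = pp.demodulate(pp.reshape_frames(pp.decode_stream(rec.raw_bytes)))
        vol = rec.breath.volume_at(mat.frame_times + 0.25)
        best_r = 0.0
        for row in mat.values:
            if row.std() > 0:
                best_r = max(best_r, abs(np.corrcoef(row, vol)[0, 1]))
        assert best_r > 0.9
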