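"""Filtering, detection, window extraction and conditioning contracts."""

import numpy as np
import pytest

from umapsort.errors import ParameterError
from umapsort.evaluate import match_spikes
from umapsort.io import Recording, SpikeEvents, WaveformSet
from umapsort.preprocess import (
    DetectConfig,
    bandpass_filter,
    condition_waveforms,
    detect_spikes,
    extract_windows,
)
from umapsort.synth import SynthSpec, render_recording

FS = 24000.0


def _sine(freq, duration=1.0):
    t = np.arange(int(FS * duration)) / FS
    return Recording(samples=np.sin(2 * np.pi * freq * t)[None, :], rate=FS)


class TestBandpass:
    def test_stopband_attenuation_at_100hz(self):
        out = bandpass_filter(_sine(100.0))
        rms_in = 1 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(out.samples[0] ** 2))
        assert 20 * np.log10(rms_in / rms_out) > 20

    def test_passband_at_1khz(self):
        out = bandpass_filter(_sine(1000.0))
        # ignore filtfilt edge transients
        mid = out.samples[0][2000:-2000]
        rms_out = np.sqrt(np.mean(mid**2))
        assert abs(20 * np.log10(rms_out / (1 / np.sqrt(2)))) < 1

    def test_dc_removed(self):
        rec = Recording(samples=np.full((1, 24000), 5.0), rate=FS)
        out = bandpass_filter(rec)
        assert np.max(np.abs(out.samples)) < 5.0 * 1e-6

    def test_infeasible_band_raises(self):
        rec = Recording(samples=np.zeros((1, 100)), rate=3000.0)
        with pytest.raises(ParameterError):
            bandpass_filter(rec)

    def test_length_preserved(self):
        out = bandpass_filter(_sine(700.0, 0.25))
        assert out.n_samples == int(FS * 0.25)


class TestDetect:
    def test_synthetic_low_noise_recall(self):
        spec = SynthSpec(n_units=3, rate_hz=20.0, duration_s=10.0, eta=0.05, seed=0)
        rec, gt = render_recording(spec)
        events = detect_spikes(bandpass_filter(rec), 0)
        all_gt = np.sort(np.concatenate([u.times for u in gt.units]))
        counts = match_spikes(events.times, all_gt, epsilon=2)
        assert counts.tp / counts.n_gt >= 0.95

    def test_gaussian_noise_false_event_rate(self, rng):
        x = rng.standard_normal(int(10 * FS))
        events = detect_spikes(Recording(samples=x[None, :], rate=FS), 0)
        assert len(events) / 10.0 < 20

    def test_dead_time_merges_to_deeper_trough(self):
        x = np.zeros(2000)
        x[500] = -1.0
        x[512] = -2.0  # 0.5 ms later, deeper
        rec = Recording(samples=x[None, :], rate=FS)
        events = detect_spikes(rec, 0, DetectConfig(k_sigma=4.0, dead_time_ms=1.0))
        np.testing.assert_array_equal(events.times, [512])

    def test_all_zero_trace_empty(self):
        events = detect_spikes(Recording(samples=np.zeros((1, 1000)), rate=FS), 0)
        assert len(events) == 0

    def test_noise_free_recovery_is_exact(self, small_recording):
        rec, gt = small_recording
        events = detect_spikes(rec, 0)
        all_gt = np.sort(np.concatenate([u.times for u in gt.units]))
        counts = match_spikes(events.times, all_gt, epsilon=2)
        assert counts.tp == counts.n_gt  # TP rate 1.0 at eps = 2 samples


class TestExtractWindows:
    def test_default_window_width_61(self, small_recording):
        rec, gt = small_recording
        ev = SpikeEvents(channel=0, times=gt.units[0].times, rate=rec.rate)
        ws = extract_windows(rec, 0, ev)
        assert ws.waves.shape[1] == 61
        assert ws.align_index == 30

    def test_edge_events_dropped(self):
        rec = Recording(samples=np.zeros((1, 1000)), rate=FS)
        ev = SpikeEvents(channel=0, times=np.array([10, 500]))
        ws = extract_windows(rec, 0, ev)
        assert ws.n_spikes == 1
        np.testing.assert_array_equal(ws.events.times, [500])

    def test_empty_events(self):
        rec = Recording(samples=np.zeros((1, 1000)), rate=FS)
        ws = extract_windows(rec, 0, SpikeEvents(channel=0, times=np.empty(0, np.int64)))
        assert ws.n_spikes == 0


class TestConditioning:
    def test_savgol_preserves_cubics(self):
        x = np.arange(61, dtype=float)
        rows = np.array([0.01 * x**3 - 0.5 * x**2 + 2 * x - 7, (x - 30.0) ** 3])
        from scipy.signal import savgol_filter

        sm = savgol_filter(rows, 5, 3, axis=1)
        assert np.max(np.abs(sm - rows)) < 1e-9

    def test_subsample_shifts_align(self):
        from umapsort.synth import _biphasic

        x = np.arange(61, dtype=float)
        rows = np.array(
            [
                _biphasic(x - s, trough=30.0, w_neg=2.5, amp_pos=0.5, lag_pos=6.0,
                          w_pos=4.0, amp_pre=0.2, lag_pre=5.0, w_pre=3.0)
                for s in (0.0, 0.25, 0.5)
            ]
        )
        cw = condition_waveforms(WaveformSet(waves=rows, n_points=61, align_index=30))
        peak = np.max(np.abs(rows))
        for i in range(3):
            for j in range(i + 1, 3):
                rms = np.sqrt(np.mean((cw.waves[i] - cw.waves[j]) ** 2))
                assert rms < 0.05 * peak

    def test_width_and_count_preserved(self, rng):
        ws = WaveformSet(waves=rng.normal(size=(7, 61)), n_points=61, align_index=30)
        cw = condition_waveforms(ws)
        assert cw.waves.shape == ws.waves.shape

    def test_idempotent_within_tolerance(self, templates3):
        rows = np.repeat(templates3, 3, axis=0)[:, :61]
        ws = WaveformSet(waves=rows, n_points=61, align_index=30)
        c1 = condition_waveforms(ws)
        c2 = condition_waveforms(c1)
        rms = np.sqrt(np.mean((c2.waves - c1.waves) ** 2))
        assert rms < 0.01 * np.max(np.abs(c1.waves))

    def test_alignment_at_align_index(self, small_recording):
        rec, gt = small_recording
        ev = SpikeEvents(channel=0, times=gt.units[0].times[1:-1], rate=rec.rate)
        cw = condition_waveforms(extract_windows(rec, 0, ev))
        assert np.all(np.argmin(cw.waves, axis=1) == cw.align_index)

    def test_bad_sg_window_raises(self, rng):
        ws = WaveformSet(waves=rng.normal(size=(2, 61)), n_points=61, align_index=30)
        with pytest.raises(ParameterError):
            condition_waveforms(ws, sg_window=4)
        with pytest.raises(ParameterError):
            condition_waveforms(ws, sg_window=61)
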