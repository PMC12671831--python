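"""Generator contracts: templates, spike trains, perturbations, rendering."""

import numpy as np
import pytest

from umapsort.errors import ParameterError
from umapsort.io import GroundTruthUnit
from umapsort.synth import (
    MEASpec,
    PerturbationSpec,
    SynthSpec,
    apply_perturbation,
    canonical_trough_index,
    generate_spike_train,
    generate_templates,
    render_mea,
    render_recording,
)


class TestTemplates:
    def test_peak_normalized_to_one(self):
        T = generate_templates(5, 64, seed=0)
        np.testing.assert_allclose(np.max(np.abs(T), axis=1), 1.0)

    def test_deterministic_per_seed(self):
        np.testing.assert_array_equal(
            generate_templates(4, 64, seed=9), generate_templates(4, 64, seed=9)
        )

    def test_shape_and_pairwise_correlation(self):
        T = generate_templates(3, 64, seed=1)
        assert T.shape == (3, 64)
        C = np.corrcoef(T)
        off = C[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.99)

    def test_trough_at_canonical_index(self):
        T = generate_templates(4, 64, seed=2)
        assert np.all(np.argmin(T, axis=1) == canonical_trough_index(64))


class TestSpikeTrains:
    def test_constant_rate_spacing(self):
        t = generate_spike_train(20.0, 10.0, fs=24000.0, mode="constant", seed=0)
        assert t.size == 200
        np.testing.assert_array_equal(np.diff(t), 1200)  # 50 ms at 24 kHz

    def test_poisson_mean_count(self):
        counts = [
            generate_spike_train(20.0, 100.0, mode="poisson", seed=s).size
            for s in range(50)
        ]
        # Poisson(2000): mean within 3 * sqrt(2000 / 50) of 2000
        assert abs(np.mean(counts) - 2000) < 3 * np.sqrt(2000 / 50)

    def test_refractory_enforced(self):
        for s in range(10):
            t = generate_spike_train(
                100.0, 20.0, mode="poisson", refractory_ms=2.0, seed=s
            )
            assert np.min(np.diff(t)) >= 2e-3 * 24000

    def test_infeasible_refractory_raises(self):
        with pytest.raises(ParameterError):
            generate_spike_train(600.0, 1.0, mode="poisson", refractory_ms=2.0)


def _unit(times, scales=None):
    times = np.asarray(times, dtype=np.int64)
    return GroundTruthUnit(
        unit_id=0,
        times=times,
        scales=np.ones(times.size) if scales is None else np.asarray(scales),
        template_id=0,
    )


class TestPerturbations:
    def test_shape_morph_endpoints_and_midpoint(self, templates3):
        u = _unit([100, 200, 300])
        spec = PerturbationSpec(kind="shape_morph", morph_templates=(0, 1))
        out = apply_perturbation(u, spec, templates3, fs=24000.0, duration_s=1.0)
        np.testing.assert_allclose(out.shapes[0], templates3[0])
        np.testing.assert_allclose(out.shapes[1], (templates3[0] + templates3[1]) / 2)
        np.testing.assert_allclose(out.shapes[2], templates3[1])

    def test_amp_drift_endpoints(self, templates3):
        dur, fs = 1.0, 24000.0
        u = _unit([0, int(dur * fs) - 1])
        spec = PerturbationSpec(kind="amp_drift")
        out = apply_perturbation(u, spec, templates3, fs=fs, duration_s=dur)
        np.testing.assert_allclose(out.scales, [1.0, 0.3], atol=1e-9)

    def test_dilution_binomial_count(self, templates3):
        n = 10_000
        u = _unit(np.arange(n) * 10)
        spec = PerturbationSpec(kind="dilution", fraction=0.2)
        out = apply_perturbation(u, spec, templates3, fs=24000.0, duration_s=10_000.0, seed=4)
        assert abs(len(out) - 2000) < 3 * np.sqrt(n * 0.2 * 0.8)

    def test_bursting_triplets_and_isi_stats(self, templates3):
        n = 3000
        u = _unit(np.arange(n) * 2400)  # 100 ms apart
        spec = PerturbationSpec(kind="bursting")
        out = apply_perturbation(u, spec, templates3, fs=24000.0, duration_s=n * 0.1, seed=0)
        assert len(out) == 3 * n
        scales = out.scales.reshape(-1, 3)
        np.testing.assert_allclose(scales, np.tile([1.0, 0.7, 0.5], (n, 1)))
        isis_ms = np.diff(out.times.reshape(-1, 3), axis=1) / 24.0
        assert np.all(isis_ms >= 1.0 - 0.05) and np.all(isis_ms <= 5.0 + 0.05)
        assert 2.5 < isis_ms.mean() < 3.5

    def test_amp_jitter_range(self, templates3):
        u = _unit(np.arange(1000) * 100)
        spec = PerturbationSpec(kind="amp_jitter")
        out = apply_perturbation(u, spec, templates3, fs=24000.0, duration_s=100.0, seed=1)
        assert out.scales.min() >= 0.5 and out.scales.max() <= 1.0


class TestRendering:
    def test_noise_free_trace_is_exact_superposition(self, small_recording):
        rec, gt = small_recording
        trough = canonical_trough_index(64)
        manual = np.zeros(rec.n_samples)
        for u in gt.units:
            shape = gt.templates[u.template_id]
            for t, s in zip(u.times, u.scales):
                lo = t - trough
                manual[lo : lo + 64] += s * shape
        np.testing.assert_allclose(rec.samples[0], manual, atol=1e-6)

    def test_noise_free_gaps_are_zero(self, small_recording):
        rec, gt = small_recording
        occupied = np.zeros(rec.n_samples, dtype=bool)
        trough = canonical_trough_index(64)
        for u in gt.units:
            for t in u.times:
                occupied[max(t - trough, 0) : t - trough + 64] = True
        assert np.all(rec.samples[0][~occupied] == 0)

    def test_background_sd_matches_eta(self):
        spec = SynthSpec(n_units=1, rate_hz=1.0, duration_s=10.0, eta=0.1, seed=0)
        rec, gt = render_recording(spec)
        occupied = np.zeros(rec.n_samples, dtype=bool)
        trough = canonical_trough_index(64)
        for t in gt.units[0].times:
            occupied[max(t - trough, 0) : t - trough + 64] = True
        sd = rec.samples[0][~occupied].std()
        assert abs(sd - 0.1) / 0.1 < 0.1

    def test_deterministic_per_seed(self):
        spec = SynthSpec(n_units=2, duration_s=2.0, eta=0.1, seed=11)
        r1, g1 = render_recording(spec)
        r2, g2 = render_recording(spec)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        for a, b in zip(g1.units, g2.units):
            np.testing.assert_array_equal(a.times, b.times)
            np.testing.assert_array_equal(a.scales, b.scales)

    def test_gt_count_matches_rendered_units(self):
        spec = SynthSpec(
            n_units=2,
            duration_s=5.0,
            eta=0.0,
            seed=2,
            perturbations=[PerturbationSpec(kind="dilution", unit=1, fraction=0.5)],
        )
        _, gt = render_recording(spec)
        assert gt.n_spikes == sum(len(u) for u in gt.units)
        assert len(gt.units[1]) < len(gt.units[0])

    def test_too_short_duration_raises(self):
        with pytest.raises(ParameterError):
            render_recording(SynthSpec(n_units=1, duration_s=64 / 48000, rate=24000.0))


class TestMEA:
    def test_attenuation_ratio_and_shared_times(self):
        spec = MEASpec(
            n_units=1, duration_s=2.0, eta=0.0, seed=0,
            grid_shape=(3, 3), pitch_um=16.0, lambda_space_um=27.0,
        )
        rec, gt = render_mea(spec)
        u = gt.units[0]
        center = 4  # (1,1) of the 3x3 grid
        neighbor = 1  # (0,1), one pitch away
        a_c = -rec.samples[center][u.times].min()
        # trough samples are shared; compare amplitudes at the same times
        ratio = rec.samples[neighbor][u.times].min() / rec.samples[center][u.times].min()
        assert a_c > 0
        np.testing.assert_allclose(ratio, np.exp(-16.0 / 27.0), rtol=1e-6)

    def test_far_electrode_below_noise(self):
        # 4 pitches away: exp(-64/27) ~ 0.094 < 1 sigma of eta = 0.1 noise
        assert np.exp(-64.0 / 27.0) < 0.1

    def test_mea_determinism(self):
        spec = MEASpec(n_units=1, duration_s=1.0, eta=0.05, seed=5, grid_shape=(3, 3))
        r1, _ = render_mea(spec)
        r2, _ = render_mea(spec)
        np.testing.assert_array_equal(r1.samples, r2.samples)
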