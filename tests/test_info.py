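"""Firing rates, plug-in mutual information, permutation significance."""

import numpy as np
import pytest

from umapsort.errors import ParameterError
from umapsort.info import (
    RateSeries,
    TrialSet,
    firing_rate,
    mi_plugin_bias_bits,
    mi_significance,
    mutual_information,
)
from umapsort.info import _mi_from_joint, _quantile_codes


def brute_force_mi(joint):
    """Explicit double loop over the printed plug-in formula (base 2)."""
    n = joint.sum()
    p_rs = joint / n
    p_r = p_rs.sum(axis=1)
    p_s = p_rs.sum(axis=0)
    mi = 0.0
    for i in range(joint.shape[0]):
        for k in range(joint.shape[1]):
            cond = p_rs[i, k] / p_s[k] if p_s[k] > 0 else 0.0  # P(r_i | s_k)
            if cond > 0 and p_r[i] > 0:
                mi += cond * p_s[k] * np.log2(cond / p_r[i])
    return mi


class TestFiringRate:
    def test_constant_train_gives_constant_rate(self):
        ts = TrialSet(
            spikes=[np.arange(0.025, 2.0, 0.05)], conditions=[0], t_start=0, t_end=2.0
        )
        rs = firing_rate(ts)
        np.testing.assert_allclose(rs.rates[0], 20.0)
        assert rs.n_bins == int(np.floor((2.0 - 0.2) / 0.02)) + 1

    def test_single_spike_is_5hz(self):
        ts = TrialSet(spikes=[np.array([0.1])], conditions=[0], t_start=0, t_end=0.25)
        rs = firing_rate(ts)
        assert rs.rates[0, 0] == pytest.approx(5.0)  # 1 spike / 0.2 s

    def test_empty_trial_zero(self):
        ts = TrialSet(spikes=[np.array([])], conditions=[0], t_start=0, t_end=1.0)
        assert np.all(firing_rate(ts).rates == 0)

    def test_causality(self):
        # a spike after a bin's window end must not count in that bin
        ts = TrialSet(spikes=[np.array([0.5])], conditions=[0], t_start=0, t_end=1.0)
        rs = firing_rate(ts)
        before = rs.bin_times < 0.5
        assert np.all(rs.rates[0][before] == 0)

    def test_bad_window_raises(self):
        ts = TrialSet(spikes=[np.array([])], conditions=[0], t_start=0, t_end=1.0)
        with pytest.raises(ParameterError):
            firing_rate(ts, window_ms=0)


class TestMutualInformation:
    def test_deterministic_binary_channel_one_bit(self):
        rates = np.r_[np.zeros(20), np.full(20, 10.0)]
        cond = np.repeat([0, 1], 20)
        assert mutual_information(rates, cond, 8) == pytest.approx(1.0)

    def test_four_conditions_two_bits(self):
        rates = np.repeat([0.0, 5.0, 10.0, 15.0], 10)
        cond = np.repeat([0, 1, 2, 3], 10)
        assert mutual_information(rates, cond, 8) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        joint = rng.integers(0, 20, size=(6, 3)).astype(float)
        joint[0, 0] += 1  # never all-zero
        assert _mi_from_joint(joint) == pytest.approx(brute_force_mi(joint), abs=1e-12)

    def test_null_within_bias_bound(self):
        rng = np.random.default_rng(0)
        n = 4000
        rates = rng.normal(size=n)
        cond = rng.integers(0, 2, size=n)  # independent of rates
        mi = mutual_information(rates, cond, 8)
        bound = mi_plugin_bias_bits(8, 2, n)
        assert 0 <= mi <= 3 * bound

    def test_ceiling_log2_m(self, rng):
        for _ in range(10):
            rates = rng.normal(size=60)
            cond = rng.integers(0, 3, size=60)
            mi = mutual_information(rates, cond, 8)
            assert 0 <= mi <= np.log2(3) + 1e-12

    def test_condition_with_too_few_trials_raises(self):
        with pytest.raises(ParameterError):
            mutual_information(np.arange(5.0), [0, 0, 0, 0, 1], 4)


class TestSignificance:
    def _null_series(self, seed, n_trials=40, n_bins=12):
        rng = np.random.default_rng(seed)
        rates = rng.poisson(4.0, size=(n_trials, n_bins)).astype(float)
        cond = np.repeat([0, 1], n_trials // 2)
        rs = RateSeries(rates=rates, bin_times=np.arange(n_bins) * 0.02 + 0.2)
        return rs, cond

    def test_p_value_range_and_determinism(self):
        rs, cond = self._null_series(1)
        r1 = mi_significance(rs, cond, n_perm=100, seed=5)
        r2 = mi_significance(rs, cond, n_perm=100, seed=5)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        assert np.all(r1.p_values >= 1 / 101) and np.all(r1.p_values <= 1.0)

    def test_strong_effect_survives_as_one_cluster(self):
        rng = np.random.default_rng(2)
        n_trials, n_bins = 40, 30
        rates = rng.normal(10.0, 1.0, size=(n_trials, n_bins))
        cond = np.repeat([0, 1], 20)
        rates[cond == 1, 5:25] += 5.0  # 5 sigma shift over 20 consecutive bins
        rs = RateSeries(rates=np.clip(rates, 0, None), bin_times=np.arange(n_bins) * 0.02)
        res = mi_significance(rs, cond, n_perm=200, seed=0, cluster_min_bins=5)
        assert res.significant_clusters == [(5, 25)]
        assert np.all(res.mi_corrected[5:25] > 0)

    def test_isolated_significant_bin_removed(self):
        rng = np.random.default_rng(3)
        n_trials, n_bins = 40, 15
        rates = rng.normal(10.0, 1.0, size=(n_trials, n_bins))
        cond = np.repeat([0, 1], 20)
        rates[cond == 1, 7] += 6.0  # single informative bin
        rs = RateSeries(rates=np.clip(rates, 0, None), bin_times=np.arange(n_bins) * 0.02)
        res = mi_significance(rs, cond, n_perm=200, seed=0, cluster_min_bins=5)
        assert res.p_values[7] < 0.05
        assert res.significant_clusters == []

    def test_low_n_perm_warns_and_tiny_raises(self):
        rs, cond = self._null_series(4)
        with pytest.warns(UserWarning):
            mi_significance(rs, cond, n_perm=50, seed=0)
        with pytest.raises(ParameterError):
            mi_significance(rs, cond, n_perm=5, seed=0)

    def test_merging_opposite_tuning_caps_mi(self):
        # two units with opposite condition tuning: the merged train's MI
        # stays at or below the better unit's MI on almost every bin
        ok_frac = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cond = np.repeat([0, 1], 20)
            mk = lambda lo, hi: [
                np.sort(rng.uniform(0, 0.6, rng.poisson((lo, hi)[int(c)] * 0.6)))
                for c in cond
            ]
            a, b = mk(5, 15), mk(15, 5)
            merged = [np.sort(np.r_[x, y]) for x, y in zip(a, b)]
            mi = {}
            for name, spikes in (("a", a), ("b", b), ("m", merged)):
                rs = firing_rate(
                    TrialSet(spikes=spikes, conditions=cond, t_start=0, t_end=0.6)
                )
                mi[name] = np.array(
                    [
                        mutual_information(rs.rates[:, j], cond, 8)
                        for j in range(rs.n_bins)
                    ]
                )
            ok = mi["m"] <= np.maximum(mi["a"], mi["b"]) + 1e-12
            ok_frac.append(ok.mean())
        assert np.mean(ok_frac) >= 0.9
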