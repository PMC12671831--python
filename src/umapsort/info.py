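"""Firing-rate estimation and mutual-information encoding analysis.

Rates are computed trial-by-trial in overlapping rectangular *causal*
windows (default 200 ms long, 20 ms step). Mutual information between the
binned rate r and the condition s at each time bin,

    I(r; s) = sum_i sum_k P(r_i | s_k) P(s_k) log2( P(r_i | s_k) / P(r_i) ),

uses a plug-in estimate on quantile-discretized rates. Significance comes
from a permutation null (condition labels shuffled across trials, the
same shuffles reused across time bins); finite-sampling bias is corrected
by subtracting the permutation-mean MI, and multiple comparisons are
handled by keeping only runs of consecutive significant bins of a
predefined minimum length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np

from .errors import ParameterError, ValidationError


@dataclass
class TrialSet:
    """Per-trial spike times (seconds, relative to the alignment event)
    plus one condition label per trial."""

    spikes: list[np.ndarray]
    conditions: np.ndarray
    t_start: float = 0.0
    t_end: float = 1.0
    alignment: str = ""

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=np.float64) for s in self.spikes]
        self.conditions = np.asarray(self.conditions)
        if len(self.spikes) != self.conditions.size:
            raise ValidationError("one condition label per trial required")
        if self.t_end <= self.t_start:
            raise ValidationError("t_end must exceed t_start")

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def condition_labels(self) -> np.ndarray:
        return np.unique(self.conditions)

    def priors(self) -> np.ndarray:
        labels = self.condition_labels
        return np.array([(self.conditions == c).mean() for c in labels])


@dataclass
class RateSeries:
    """(n_trials, n_bins) firing rates in Hz; bin stamps are window ends."""

    rates: np.ndarray
    bin_times: np.ndarray
    window_ms: float = 200.0
    step_ms: float = 20.0

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=np.float64))
        if np.any(self.rates < 0):
            raise ValidationError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


@dataclass
class MIResult:
    mi_bits: np.ndarray
    mi_corrected: np.ndarray
    p_values: np.ndarray
    significant_clusters: list[tuple[int, int]]  # [start, stop) bin runs
    n_perm: int
    alpha: float
    n_rate_bins: int

    @property
    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.mi_bits.size, dtype=bool)
        for a, b in self.significant_clusters:
            mask[a:b] = True
        return mask


def firing_rate(
    trialset: TrialSet, window_ms: float = 200.0, step_ms: float = 20.0
) -> RateSeries:
    """Causal windowed rates: bin at time t counts spikes in (t - window, t]."""
    if window_ms <= 0 or step_ms <= 0:
        raise ParameterError("window and step must be positive")
    window = window_ms / 1000.0
    step = step_ms / 1000.0
    total = trialset.t_end - trialset.t_start
    if total < window:
        raise ParameterError("trial duration shorter than one window")
    n_bins = int(np.floor((total - window) / step)) + 1
    ends = trialset.t_start + window + step * np.arange(n_bins)
    rates = np.zeros((trialset.n_trials, n_bins))
    for i, spk in enumerate(trialset.spikes):
        if spk.size == 0:
            continue
        # count spikes in (end - window, end]
        hi = np.searchsorted(np.sort(spk), ends, side="right")
        lo = np.searchsorted(np.sort(spk), ends - window, side="right")
        rates[i] = (hi - lo) / window
    return RateSeries(rates=rates, bin_times=ends, window_ms=window_ms, step_ms=step_ms)


# ---------------------------------------------------------------------------
# Discretization and plug-in MI
# ---------------------------------------------------------------------------


def _quantile_codes(values: np.ndarray, n_rate_bins: int) -> np.ndarray:
    """Discretize pooled rates into quantile bins; returns integer codes."""
    edges = np.quantile(values, np.linspace(0, 1, n_rate_bins + 1))
    inner = np.unique(edges[1:-1])
    return np.searchsorted(inner, values, side="right")


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """Base-2 MI for a stack of joint count tables (..., n_r, n_s)."""
    n = joint.sum(axis=(-2, -1), keepdims=True)
    p = joint / np.where(n == 0, 1, n)
    pr = p.sum(axis=-1, keepdims=True)
    ps = p.sum(axis=-2, keepdims=True)
    denom = pr * ps
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(np.where(p > 0, p / np.where(denom > 0, denom, 1), 1))
    return term.sum(axis=(-2, -1))


def _condition_codes(conditions: np.ndarray) -> tuple[np.ndarray, int]:
    labels, codes = np.unique(np.asarray(conditions), return_inverse=True)
    return codes, labels.size


def mutual_information(
    rates_at_bin, conditions, n_rate_bins: int = 8
) -> float:
    """Plug-in MI (bits) between quantile-binned rates and conditions."""
    r = np.asarray(rates_at_bin, dtype=np.float64)
    y, n_cond = _condition_codes(conditions)
    if n_cond < 2:
        raise ParameterError("MI needs at least 2 conditions")
    counts = np.bincount(y)
    if np.any(counts < 2):
        raise ParameterError("each condition needs at least 2 trials")
    codes = _quantile_codes(r, n_rate_bins)
    n_r = int(codes.max()) + 1
    joint = np.zeros((n_r, n_cond))
    np.add.at(joint, (codes, y), 1.0)
    return float(_mi_from_joint(joint))


def mi_plugin_bias_bits(n_rate_bins: int, n_conditions: int, n_trials: int) -> float:
    """First-order plug-in bias, (N_r - 1)(M - 1) / (2 n ln 2) bits."""
    return (n_rate_bins - 1) * (n_conditions - 1) / (2 * n_trials * np.log(2))


def mi_significance(
    rateseries: RateSeries,
    conditions,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_rate_bins: int = 8,
    cluster_min_bins: int = 5,
    seed: int = 0,
) -> MIResult:
    """Per-bin MI with permutation p-values and cluster-size correction.

    The same trial shuffles are reused across bins within a permutation
    draw; p = (1 + #{perm MI >= observed}) / (n_perm + 1); the
    bias-corrected MI subtracts the permutation mean; surviving clusters
    are maximal runs of consecutive significant bins with length >=
    ``cluster_min_bins``.
    """
    if n_perm < 10:
        raise ParameterError("n_perm must be at least 10")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable p-values")
    y, n_cond = _condition_codes(conditions)
    if n_cond < 2:
        raise ParameterError("MI needs at least 2 conditions")
    rates = rateseries.rates
    n_trials, n_bins = rates.shape
    if y.size != n_trials:
        raise ParameterError("one condition per trial required")

    # per-bin quantile codes -> one-hot (n_bins, n_r, n_trials)
    codes = np.stack(
        [_quantile_codes(rates[:, b], n_rate_bins) for b in range(n_bins)], axis=1
    )  # (n_trials, n_bins)
    n_r = int(codes.max()) + 1
    onehot = np.zeros((n_bins, n_r, n_trials))
    onehot[np.arange(n_bins)[None, :], codes, np.arange(n_trials)[:, None]] = 1.0
    y_onehot = np.zeros((n_trials, n_cond))
    y_onehot[np.arange(n_trials), y] = 1.0

    observed = _mi_from_joint(onehot @ y_onehot)  # (n_bins,)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n_trials) for _ in range(n_perm)])
    # joint counts for all permutations at once: (n_perm, n_bins, n_r, n_cond)
    joints = np.einsum("brt,ptc->pbrc", onehot, y_onehot[perms])
    perm_mi = _mi_from_joint(joints)

    p_values = (1.0 + (perm_mi >= observed[None, :]).sum(axis=0)) / (n_perm + 1.0)
    corrected = observed - perm_mi.mean(axis=0)
    significant = p_values < alpha

    clusters: list[tuple[int, int]] = []
    b = 0
    while b < n_bins:
        if significant[b]:
            start = b
            while b < n_bins and significant[b]:
                b += 1
            if b - start >= cluster_min_bins:
                clusters.append((start, b))
        else:
            b += 1
    return MIResult(
        mi_bits=observed,
        mi_corrected=corrected,
        p_values=p_values,
        significant_clusters=clusters,
        n_perm=n_perm,
        alpha=alpha,
        n_rate_bins=n_rate_bins,
    )
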