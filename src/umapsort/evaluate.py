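"""Ground-truth spike matching, precision/recall/F1, inclusion matrices.

Matching is one-to-one: a burst triplet cannot claim the same ground-truth
spike three times. For each ground-truth spike in time order the earliest
still-unmatched sorted spike within the tolerance is taken; this greedy
sweep attains the maximum possible number of matches (it is exchange-
equivalent to the optimal assignment on sorted trains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError

DEFAULT_EPSILON_MS = 0.5  # 12 samples at 24 kHz


@dataclass
class MatchCounts:
    tp: int
    fp: int
    fn: int
    epsilon: float
    n_sorted: int
    n_gt: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("counts must be non-negative")
        if self.tp + self.fp != self.n_sorted or self.tp + self.fn != self.n_gt:
            raise ValidationError("counts inconsistent with train sizes")


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float

    @classmethod
    def zero(cls) -> "Metrics":
        return cls(0.0, 0.0, 0.0)


def match_spikes(sorted_times, gt_times, epsilon: float) -> MatchCounts:
    """One-to-one match of a sorted train against ground truth within ε.

    Both trains must be sorted ascending; times and ε share one unit
    (samples or milliseconds).
    """
    if epsilon < 0:
        raise ParameterError("epsilon must be non-negative")
    s = np.asarray(sorted_times, dtype=np.float64)
    g = np.asarray(gt_times, dtype=np.float64)
    if np.any(np.diff(s) < 0) or np.any(np.diff(g) < 0):
        raise ValidationError("spike trains must be sorted ascending")
    tp = 0
    i = 0  # first candidate sorted spike not yet consumed
    for t in g:
        while i < s.size and s[i] < t - epsilon:
            i += 1
        if i < s.size and abs(s[i] - t) <= epsilon:
            tp += 1
            i += 1
    return MatchCounts(
        tp=tp,
        fp=int(s.size - tp),
        fn=int(g.size - tp),
        epsilon=float(epsilon),
        n_sorted=int(s.size),
        n_gt=int(g.size),
    )


def compute_metrics(counts: MatchCounts) -> Metrics:
    """Precision, recall and F1 with the 0/0 -> 0 conventions."""
    p = counts.tp / counts.n_sorted if counts.n_sorted else 0.0
    r = counts.tp / counts.n_gt if counts.n_gt else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return Metrics(precision=p, recall=r, f1=f1)


def f1_against_gt(sorted_times, gt_times, epsilon: float) -> Metrics:
    return compute_metrics(match_spikes(sorted_times, gt_times, epsilon))


@dataclass
class InclusionMatrix:
    """Entry (i, j): percentage of spikes of train i also present in train j."""

    values: np.ndarray  # (n_trains, n_trains), 0-100
    train_ids: list


def inclusion_matrix(trains, epsilon: float, train_ids=None) -> InclusionMatrix:
    """Pairwise inclusion indices (percent), generally asymmetric.

    With a ground-truth train among the inputs, its row equals 100·recall
    and its column 100·precision of each other train against it.
    """
    trains = [np.asarray(t, dtype=np.float64) for t in trains]
    if len(trains) < 2:
        raise ParameterError("need at least 2 trains")
    n = len(trains)
    if train_ids is None:
        train_ids = list(range(n))
    values = np.zeros((n, n))
    for i, si in enumerate(trains):
        if si.size == 0:
            warnings.warn(f"train {train_ids[i]} is empty; row set to 0")
            continue
        for j, sj in enumerate(trains):
            if i == j:
                values[i, j] = 100.0
                continue
            counts = match_spikes(si, sj, epsilon)
            values[i, j] = 100.0 * counts.tp / si.size
    return InclusionMatrix(values=values, train_ids=list(train_ids))
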