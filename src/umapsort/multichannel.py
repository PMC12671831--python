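"""Multielectrode-array analysis: hotspot selection, super-waveforms,
concentric-ring geometric analysis, spatial F1 maps and decay fitting.

A "hotspot" is the electrode carrying the strongest signal from a unit;
spike times detected there serve as the temporal reference for snippet
concatenation across neighboring electrodes. Rings around the hotspot are
square shells on the electrode grid (Chebyshev distance); physical
Euclidean distances in micrometres are kept for the F1-vs-distance
profile and the exponential decay fit F1(x) = A exp(-x/tau) + B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .cluster import ClusterConfig, cluster_hdbscan, select_best_unit
from .errors import DegenerateFitError, FitError, ParameterError
from .evaluate import Metrics
from .features import embed_umap
from .io import Geometry, Recording, SpikeEvents, WaveformSet
from .preprocess import DetectConfig, condition_waveforms, detect_spikes, extract_windows

logger = logging.getLogger(__name__)


@dataclass
class RingPartition:
    center: int  # channel index
    rings: list[list[int]]  # ring r = channels at Chebyshev distance r (ring 0 = center)
    distances_um: dict[int, float]  # per-channel Euclidean distance from center

    def cumulative(self, r: int) -> list[int]:
        """Channels within rings 0..r, in canonical (row-major grid) order."""
        chans = [c for ring in self.rings[: r + 1] for c in ring]
        return sorted(chans)

    @property
    def n_rings(self) -> int:
        return len(self.rings)


@dataclass
class DecayFit:
    A: float
    tau: float  # micrometres
    B: float
    residual_rms: float
    n_points: int
    success: bool = True


# ---------------------------------------------------------------------------


def _snippet_trough_depth(x: np.ndarray, times: np.ndarray, pre: int, post: int) -> float:
    ok = (times >= pre) & (times + post < x.size)
    times = times[ok]
    if times.size == 0:
        return -np.inf
    idx = times[:, None] + np.arange(-pre, post + 1)[None, :]
    return float(np.mean(-x[idx].min(axis=1)))


def find_hotspot(
    recording: Recording,
    gt_or_events,
    pre: int = 30,
    post: int = 30,
) -> int:
    """Channel with the largest mean trough amplitude at the reference times.

    ``gt_or_events`` is either a GroundTruthUnit / SpikeEvents or a plain
    array of spike times. Ties go to the lowest channel index.
    """
    times = np.asarray(getattr(gt_or_events, "times", gt_or_events), dtype=np.int64)
    if times.size == 0:
        raise ParameterError("no reference events to locate a hotspot")
    depths = [
        _snippet_trough_depth(recording.samples[c].astype(np.float64), times, pre, post)
        for c in range(recording.n_channels)
    ]
    if not np.isfinite(np.max(depths)):
        raise ParameterError("no events fall inside the recording on any channel")
    return int(np.argmax(depths))  # argmax takes the first (lowest) on ties


def _canonical_order(geometry: Geometry, channels: Sequence[int]) -> list[int]:
    return sorted(channels, key=lambda c: tuple(geometry.coords[c]))


def concatenate_snippets(
    recording: Recording,
    ref_events: SpikeEvents,
    channels: Sequence[int],
    pre: int = 30,
    post: int = 30,
) -> WaveformSet:
    """Super-waveforms: per-spike snippets concatenated across channels.

    Channels are canonicalized to ascending (i, j) row-major order, so a
    permuted input channel list yields an identical result. Events too
    near an edge are dropped consistently across channels.
    """
    if recording.geometry is None:
        raise ParameterError("concatenation requires electrode geometry")
    channels = _canonical_order(recording.geometry, channels)
    n = recording.n_samples
    times = ref_events.times
    ok = (times >= pre) & (times + post < n)
    times = times[ok]
    width = pre + post + 1
    if times.size == 0:
        waves = np.empty((0, width * len(channels)))
    else:
        idx = times[:, None] + np.arange(-pre, post + 1)[None, :]
        blocks = [recording.samples[c][idx].astype(np.float64) for c in channels]
        waves = np.concatenate(blocks, axis=1)
    return WaveformSet(
        waves=waves,
        n_points=width,
        align_index=pre,
        events=SpikeEvents(channel=ref_events.channel, times=times, rate=recording.rate),
        channel_order=list(channels),
    )


def ring_partition(geometry: Geometry, center: int, patch: int = 5) -> RingPartition:
    """Square shells (Chebyshev rings) of a patch x patch block around center."""
    if patch % 2 == 0:
        raise ParameterError("patch must be odd")
    ci, cj = geometry.coords[center]
    half = patch // 2
    rings: list[list[int]] = [[] for _ in range(half + 1)]
    truncated = False
    for c, (i, j) in enumerate(geometry.coords):
        r = max(abs(i - ci), abs(j - cj))
        if r <= half:
            rings[r].append(c)
    expected = [1] + [8 * r for r in range(1, half + 1)]
    if [len(r) for r in rings] != expected:
        truncated = True
        logger.warning("patch truncated at the array border around channel %d", center)
    rings = [r for r in rings if r]
    pos = geometry.positions_um()
    distances = {
        c: float(np.linalg.norm(pos[c] - pos[center]))
        for ring in rings
        for c in ring
    }
    _ = truncated
    return RingPartition(center=center, rings=rings, distances_um=distances)


# ---------------------------------------------------------------------------
# Per-electrode and cumulative pipelines
# ---------------------------------------------------------------------------


def _sort_waveset(
    ws: WaveformSet,
    gt_times: np.ndarray,
    epsilon: float,
    cluster_config: ClusterConfig,
    seed: int,
) -> Metrics:
    if ws.n_spikes <= 15:  # not enough points to embed
        return Metrics.zero()
    # super-waveforms align on the reference (hotspot) channel's block so
    # every block follows the reference trough, not a far noisy electrode
    align_block = 0
    if ws.channel_order is not None and ws.events is not None:
        if ws.events.channel in ws.channel_order:
            align_block = ws.channel_order.index(ws.events.channel)
    ws = condition_waveforms(ws, align_block=align_block)
    emb = embed_umap(ws, seed=seed)
    labeling = cluster_hdbscan(emb, cluster_config)
    _, metrics = select_best_unit(labeling, ws.events.times, gt_times, epsilon)
    return metrics


def single_channel_f1(
    recording: Recording,
    channel: int,
    gt_times: np.ndarray,
    epsilon: float,
    detect_config: DetectConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    seed: int = 0,
) -> Metrics:
    """Full single-channel pipeline (detect -> window -> condition -> UMAP
    -> HDBSCAN -> best-unit F1) on one electrode."""
    detect_config = detect_config or DetectConfig()
    cluster_config = cluster_config or ClusterConfig()
    events = detect_spikes(recording, channel, detect_config)
    ws = extract_windows(recording, channel, events)
    return _sort_waveset(ws, gt_times, epsilon, cluster_config, seed)


def spatial_f1_map(
    recording: Recording,
    gt_times: np.ndarray,
    epsilon: float,
    center: Optional[int] = None,
    patch: int = 5,
    detect_config: DetectConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, RingPartition]:
    """Patch x patch matrix of per-electrode single-channel F1 scores.

    Each electrode runs the full pipeline independently (seed policy:
    base seed + channel index). Electrodes with no usable detections get
    F1 = 0.
    """
    if recording.geometry is None:
        raise ParameterError("spatial map requires electrode geometry")
    gt_times = np.asarray(gt_times, dtype=np.int64)
    if center is None:
        center = find_hotspot(recording, gt_times)
    part = ring_partition(recording.geometry, center, patch)
    ci, cj = recording.geometry.coords[center]
    half = patch // 2
    f1 = np.zeros((patch, patch))
    for c in part.cumulative(part.n_rings - 1):
        i, j = recording.geometry.coords[c]
        m = single_channel_f1(
            recording, c, gt_times, epsilon,
            detect_config=detect_config, cluster_config=cluster_config,
            seed=seed + c,
        )
        f1[i - ci + half, j - cj + half] = m.f1
    return f1, part


def geometric_analysis(
    recording: Recording,
    gt_times: np.ndarray,
    epsilon: float,
    center: Optional[int] = None,
    patch: int = 5,
    detect_config: DetectConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    seed: int = 0,
    include_full: bool = True,
) -> dict:
    """Cumulative-ring concatenation analysis around the hotspot.

    Step r concatenates snippets over rings 0..r (using hotspot spike
    times as temporal reference), embeds, clusters, and scores against the
    ground truth; the optional final entry uses all channels of the array
    at once ("full MEA").
    """
    if recording.geometry is None:
        raise ParameterError("geometric analysis requires electrode geometry")
    detect_config = detect_config or DetectConfig()
    cluster_config = cluster_config or ClusterConfig()
    gt_times = np.asarray(gt_times, dtype=np.int64)
    if center is None:
        center = find_hotspot(recording, gt_times)
    part = ring_partition(recording.geometry, center, patch)
    ref_events = detect_spikes(recording, center, detect_config)
    ring_f1: list[float] = []
    for r in range(part.n_rings):
        ws = concatenate_snippets(recording, ref_events, part.cumulative(r))
        m = _sort_waveset(ws, gt_times, epsilon, cluster_config, seed=seed + r)
        ring_f1.append(m.f1)
    out = {"center": center, "ring_f1": ring_f1, "partition": part}
    if include_full:
        all_channels = list(range(recording.n_channels))
        ws = concatenate_snippets(recording, ref_events, all_channels)
        m = _sort_waveset(ws, gt_times, epsilon, cluster_config, seed=seed + part.n_rings)
        out["full_mea_f1"] = m.f1
    return out


def distance_profile(
    f1_map: np.ndarray, part: RingPartition, geometry: Geometry, n_bins: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Bin per-electrode F1 by Euclidean distance; returns (bin centers, means)."""
    chans = part.cumulative(part.n_rings - 1)
    ci, cj = geometry.coords[part.center]
    half = f1_map.shape[0] // 2
    d = np.array([part.distances_um[c] for c in chans])
    f = np.array(
        [
            f1_map[geometry.coords[c][0] - ci + half, geometry.coords[c][1] - cj + half]
            for c in chans
        ]
    )
    # one bin per distinct distance band keeps the profile exact on a grid
    uniq = np.unique(np.round(d, 6))
    if uniq.size > n_bins:
        edges = np.linspace(0, d.max() + 1e-9, n_bins + 1)
        centers, means = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (d >= lo) & (d < hi) if hi < edges[-1] else (d >= lo) & (d <= hi)
            if mask.any():
                centers.append(d[mask].mean())
                means.append(f[mask].mean())
        return np.asarray(centers), np.asarray(means)
    means = np.array([f[np.isclose(d, u)].mean() for u in uniq])
    return uniq, means


def fit_decay(
    distances_um,
    f1_values,
    bounds_A=(0.0, 1.5),
    bounds_tau=(1e-6, 1e3),
    bounds_B=(0.0, 1.0),
) -> DecayFit:
    """Least-squares fit of F1(x) = A exp(-x/tau) + B with multi-start.

    Requires >= 4 points over >= 3 distinct distances; flat data (variance
    below 1e-6) raise a degenerate-fit error.
    """
    x = np.asarray(distances_um, dtype=np.float64)
    y = np.asarray(f1_values, dtype=np.float64)
    if x.size != y.size or x.size < 4:
        raise ParameterError("need at least 4 (distance, F1) points")
    if np.unique(np.round(x, 9)).size < 3:
        raise ParameterError("need at least 3 distinct distances")
    if np.var(y) < 1e-6:
        raise DegenerateFitError("F1 values are flat; no decay to fit")

    def resid(p):
        A, tau, B = p
        return A * np.exp(-x / tau) + B - y

    lo = [bounds_A[0], bounds_tau[0], bounds_B[0]]
    hi = [bounds_A[1], bounds_tau[1], bounds_B[1]]
    span = max(x.max() - x.min(), 1.0)
    best = None
    for tau0 in (span / 10, span / 3, span, span * 3):
        p0 = [
            np.clip(y.max() - y.min(), *bounds_A),
            np.clip(tau0, *bounds_tau),
            np.clip(y.min(), *bounds_B),
        ]
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi))
        except Exception:  # pragma: no cover - scipy failures become FitError
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("exponential decay fit failed from every start")
    A, tau, B = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return DecayFit(A=float(A), tau=float(tau), B=float(B), residual_rms=rms, n_points=x.size)
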