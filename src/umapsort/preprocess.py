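"""Filtering, spike detection, window extraction, and waveform conditioning.

The conditioning chain follows the standard practice for threshold-based
sorters: per-waveform Savitzky-Golay smoothing (order 3, window 5),
monotone piecewise-cubic Hermite (PCHIP) interpolation onto a finer grid,
trough alignment on the fine grid, and decimation back to the original
point count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .errors import ParameterError
from .io import Recording, SpikeEvents, WaveformSet

logger = logging.getLogger(__name__)


@dataclass
class DetectConfig:
    """Detection parameters.

    ``k_sigma`` multiplies the robust noise scale median(|x|)/0.6745;
    negative polarity (trough detection) is the default for extracellular
    spikes. The band (500, 2000) Hz isolates the spike-frequency range.
    """

    k_sigma: float = 4.0
    polarity: str = "negative"  # negative | positive | both
    dead_time_ms: float = 1.0
    band: tuple[float, float] = (500.0, 2000.0)
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ParameterError("k_sigma must be positive")
        if self.polarity not in ("negative", "positive", "both"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        low, high = self.band
        if not 0 < low < high:
            raise ParameterError("band must satisfy 0 < low < high")


def bandpass_filter(recording: Recording, config: DetectConfig | None = None) -> Recording:
    """Zero-phase Butterworth band-pass per channel; mean removed."""
    config = config or DetectConfig()
    low, high = config.band
    if high >= recording.rate / 2:
        raise ParameterError(
            f"band edge {high} Hz infeasible at rate {recording.rate} Hz"
        )
    sos = butter(
        config.filter_order, [low, high], btype="bandpass", fs=recording.rate, output="sos"
    )
    x = recording.samples.astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    y = sosfiltfilt(sos, x, axis=1)
    return Recording(samples=y, rate=recording.rate, geometry=recording.geometry)


def robust_sigma(x: np.ndarray) -> float:
    """Median-based noise-scale estimator, median(|x|)/0.6745."""
    return float(np.median(np.abs(x)) / 0.6745)


def detect_spikes(
    recording: Recording, channel: int = 0, config: DetectConfig | None = None
) -> SpikeEvents:
    """Threshold crossings reduced to local extrema, with dead-time merging.

    Crossing regions (|x| beyond ``k_sigma * sigma`` on the configured
    polarity) are reduced to their extremum sample; events closer than the
    dead time are merged keeping the deeper extremum.
    """
    config = config or DetectConfig()
    x = recording.samples[channel].astype(np.float64)
    sigma = robust_sigma(x)
    # a noiseless trace has sigma 0; any deflection is then a spike
    thr = config.k_sigma * sigma
    if config.polarity == "negative":
        over = x < -thr
        depth = -x
    elif config.polarity == "positive":
        over = x > thr
        depth = x
    else:
        over = np.abs(x) > thr
        depth = np.abs(x)

    if not over.any():
        return SpikeEvents(channel=channel, times=np.empty(0, np.int64), rate=recording.rate)
    # contiguous supra-threshold regions -> extremum sample per region
    edges = np.diff(over.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if over[0]:
        starts = np.r_[0, starts]
    if over[-1]:
        ends = np.r_[ends, over.size]
    peaks = np.fromiter(
        (s + int(np.argmax(depth[s:e])) for s, e in zip(starts, ends)),
        dtype=np.int64,
        count=starts.size,
    )
    # dead-time merge, keeping the larger extremum
    dead = int(round(config.dead_time_ms / 1000.0 * recording.rate))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < dead:
            if depth[p] > depth[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return SpikeEvents(channel=channel, times=np.asarray(kept, np.int64), rate=recording.rate)


def extract_windows(
    recording: Recording,
    channel: int,
    events: SpikeEvents,
    pre: int = 30,
    post: int = 30,
) -> WaveformSet:
    """Inclusive windows [t - pre, t + post] around each event.

    Events too close to an edge are dropped (counted in the log), so the
    returned WaveformSet may carry fewer rows than the input events.
    """
    x = recording.samples[channel]
    n = x.size
    times = events.times
    ok = (times >= pre) & (times + post < n)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d events too close to the recording edge", n_dropped)
    times = times[ok]
    width = pre + post + 1
    if times.size == 0:
        waves = np.empty((0, width))
    else:
        idx = times[:, None] + np.arange(-pre, post + 1)[None, :]
        waves = x[idx].astype(np.float64)
    return WaveformSet(
        waves=waves,
        n_points=width,
        align_index=pre,
        events=SpikeEvents(channel=channel, times=times, rate=recording.rate),
    )


def _trough_vertex(sm: np.ndarray, half: int = 3) -> np.ndarray:
    """Sub-sample trough location per row via a least-squares parabola.

    Fitting around the discrete minimum averages the noise over 2*half+1
    samples; picking the single deepest interpolated sample instead would
    flip by a whole sample whenever a flat trough straddles two samples.
    """
    n = sm.shape[1]
    j = np.argmin(sm, axis=1)
    out = np.empty(sm.shape[0])
    for i, jj in enumerate(j):
        lo, hi = max(jj - half, 0), min(jj + half + 1, n)
        x = np.arange(lo, hi, dtype=float)
        c = np.polyfit(x, sm[i, lo:hi], 2)
        x0 = -c[1] / (2 * c[0]) if c[0] > 0 else float(jj)
        out[i] = float(np.clip(x0, jj - 1, jj + 1))
    return out


def condition_waveforms(
    ws: WaveformSet,
    sg_order: int = 3,
    sg_window: int = 5,
    upsample_factor: int = 4,
    align_block: int = 0,
) -> WaveformSet:
    """Smooth, interpolate, align at the minimum, and downsample.

    Per row: Savitzky-Golay smoothing -> PCHIP interpolation onto a grid
    ``upsample_factor`` times finer -> shift so the trough (sub-sample
    location from a parabola fit around the minimum) sits at
    ``align_index`` -> decimation back to exactly ``n_points`` samples.
    Width and row count are preserved.

    For concatenated super-waveforms, ``align_block`` selects the channel
    block whose trough defines the alignment (normally the hotspot); all
    blocks of a row follow the same shift to stay time-locked.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ParameterError("sg_window must be odd and greater than sg_order")
    if sg_window >= ws.n_points:
        raise ParameterError("sg_window must be smaller than the waveform length")
    if ws.n_spikes == 0:
        return ws
    n = ws.n_points
    n_ch = ws.n_channels
    if not 0 <= align_block < n_ch:
        raise ParameterError("align_block out of range")
    f = int(upsample_factor)
    coarse = np.arange(n, dtype=float)
    fine = np.arange((n - 1) * f + 1, dtype=float) / f
    target = ws.align_index * f
    out = np.empty_like(ws.waves)
    ref = ws.waves[:, align_block * n : (align_block + 1) * n]
    vertices = _trough_vertex(savgol_filter(ref, sg_window, sg_order, axis=1))
    shifts = np.clip(
        np.round((ws.align_index - vertices) * f).astype(int),
        -(fine.size - 1),
        fine.size - 1,
    )
    for c in range(n_ch):
        block = ws.waves[:, c * n : (c + 1) * n]
        sm = savgol_filter(block, sg_window, sg_order, axis=1)
        dense = PchipInterpolator(coarse, sm, axis=1, extrapolate=False)(fine)
        for i, s in enumerate(shifts):
            row = dense[i]
            if s > 0:
                row = np.r_[np.full(s, row[0]), row[:-s]]
            elif s < 0:
                row = np.r_[row[-s:], np.full(-s, row[-1])]
            out[i, c * n : (c + 1) * n] = row[::f]
    return WaveformSet(
        waves=out,
        n_points=n,
        align_index=ws.align_index,
        events=ws.events,
        channel_order=ws.channel_order,
    )
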