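"""Domain types and file I/O for recordings, spike events, waveforms and ground truth.

Conventions (fixed so that downstream tests are bit-exact):

* voltages are stored little-endian float32, channel-major;
* spike times are integer sample indices, 0-based; seconds are derived
  through the sampling rate;
* windows are half-open in slicing but waveform snippets use the inclusive
  ``[t - pre, t + post]`` convention (width ``pre + post + 1``).

Units follow the simulator: spike templates are peak-normalized to 1, so
voltage is expressed in template-peak units throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_DTYPE = np.dtype("<f4")

NOISE_LABEL = -1


@dataclass
class Geometry:
    """Electrode layout: integer grid coordinates plus a pitch in micrometres."""

    coords: list[tuple[int, int]]
    pitch_um: float

    def __post_init__(self) -> None:
        self.coords = [tuple(int(v) for v in c) for c in self.coords]
        if self.pitch_um <= 0:
            raise ValidationError("pitch_um must be positive")
        if len(set(self.coords)) != len(self.coords):
            raise ValidationError("geometry coordinates must be unique")

    def positions_um(self) -> np.ndarray:
        """(n_channels, 2) array of physical positions in micrometres."""
        return np.asarray(self.coords, dtype=float) * self.pitch_um

    def distance_um(self, a: int, b: int) -> float:
        pa, pb = self.positions_um()[[a, b]]
        return float(np.hypot(*(pa - pb)))


@dataclass
class Recording:
    """Multichannel voltage trace with sampling rate and optional geometry."""

    samples: np.ndarray  # (n_channels, n_samples)
    rate: float  # Hz
    geometry: Optional[Geometry] = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float32))
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValidationError("samples must be a (n_channels, n_samples) matrix")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.geometry is not None and len(self.geometry.coords) != self.n_channels:
            raise ValidationError(
                f"geometry has {len(self.geometry.coords)} entries for "
                f"{self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class SpikeEvents:
    """Strictly increasing spike times (sample indices) on one channel."""

    channel: int
    times: np.ndarray
    rate: Optional[float] = None  # Hz, enables the seconds accessor

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.ndim != 1:
            raise ValidationError("times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValidationError("times must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    def seconds(self, rate: Optional[float] = None) -> np.ndarray:
        r = rate if rate is not None else self.rate
        if r is None:
            raise ValidationError("no sampling rate available to convert to seconds")
        return self.times / float(r)


@dataclass
class WaveformSet:
    """Aligned spike snippets, one row per spike.

    ``waves`` is either ``(n_spikes, n_points)`` for a single channel or
    ``(n_spikes, n_points * n_channels)`` for concatenated super-waveforms;
    ``align_index`` is the trough index within each per-channel window.
    """

    waves: np.ndarray
    n_points: int
    align_index: int
    events: Optional[SpikeEvents] = None
    channel_order: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.waves = np.atleast_2d(np.asarray(self.waves, dtype=np.float64))
        if not 0 <= self.align_index < self.n_points:
            raise ValidationError("align_index must lie within the window")
        if self.waves.shape[1] % self.n_points != 0:
            raise ValidationError(
                f"width {self.waves.shape[1]} not divisible by n_points {self.n_points}"
            )
        if self.events is not None and len(self.events) != self.n_spikes:
            raise ValidationError("row count must equal event count")
        if self.channel_order is not None and (
            len(self.channel_order) != self.waves.shape[1] // self.n_points
        ):
            raise ValidationError("channel_order length inconsistent with width")

    @property
    def n_spikes(self) -> int:
        return self.waves.shape[0]

    @property
    def n_channels(self) -> int:
        return self.waves.shape[1] // self.n_points


@dataclass
class GroundTruthUnit:
    unit_id: int
    times: np.ndarray  # sample indices, strictly increasing
    scales: np.ndarray  # per-spike amplitude multipliers, > 0
    template_id: int
    shapes: Optional[np.ndarray] = None  # per-spike waveforms, overrides template

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if self.times.size != self.scales.size:
            raise ValidationError("times and scales must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("unit times must be strictly increasing")
        if self.scales.size and np.any(self.scales <= 0):
            raise ValidationError("amplitude scales must be positive")
        if self.shapes is not None:
            self.shapes = np.asarray(self.shapes, dtype=np.float64)
            if self.shapes.shape[0] != self.times.size:
                raise ValidationError("per-spike shapes must match spike count")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class GroundTruth:
    """Exact spike times / scales per simulated unit plus the source templates."""

    units: list[GroundTruthUnit]
    templates: np.ndarray  # (n_templates, n_points)

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=np.float64))

    def unit(self, unit_id: int) -> GroundTruthUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no ground-truth unit {unit_id}")

    @property
    def n_spikes(self) -> int:
        return sum(len(u) for u in self.units)


@dataclass
class Labeling:
    """Integer cluster label per spike; -1 is the reserved noise label."""

    labels: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and self.labels.min() < NOISE_LABEL:
            raise ValidationError("labels must be >= -1")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != NOISE_LABEL]

    @property
    def noise_fraction(self) -> float:
        if not len(self):
            return 0.0
        return float(np.mean(self.labels == NOISE_LABEL))


# ---------------------------------------------------------------------------
# Recording I/O: flat little-endian float32 binary + JSON sidecar
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, binary_path, sidecar_path=None) -> None:
    binary_path = Path(binary_path)
    if sidecar_path is None:
        sidecar_path = binary_path.with_suffix(".json")
    rec.samples.astype(_DTYPE).tofile(binary_path)
    meta = {
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "rate": rec.rate,
        "dtype": "<f4",
        "order": "channel_major",
    }
    if rec.geometry is not None:
        meta["geometry"] = {
            "pitch_um": rec.geometry.pitch_um,
            "coords": [list(c) for c in rec.geometry.coords],
        }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def load_recording(binary_path, sidecar_path=None) -> Recording:
    binary_path = Path(binary_path)
    if sidecar_path is None:
        sidecar_path = binary_path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise ConfigError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("n_channels", "rate"):
        if key not in meta:
            raise ConfigError(f"sidecar missing required field '{key}'")
    n_channels = int(meta["n_channels"])
    raw = np.fromfile(binary_path, dtype=np.dtype(meta.get("dtype", "<f4")))
    if raw.size % n_channels != 0:
        raise FormatError(
            f"binary holds {raw.size} values, not divisible by "
            f"n_channels={n_channels}"
        )
    n_samples = raw.size // n_channels
    if "n_samples" in meta and int(meta["n_samples"]) != n_samples:
        raise FormatError(
            f"sidecar declares {meta['n_samples']} samples/channel but the "
            f"binary holds {n_samples}"
        )
    geometry = None
    if meta.get("geometry"):
        geometry = Geometry(
            coords=[tuple(c) for c in meta["geometry"]["coords"]],
            pitch_um=float(meta["geometry"]["pitch_um"]),
        )
    return Recording(
        samples=raw.reshape(n_channels, n_samples),
        rate=float(meta["rate"]),
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# Event CSV I/O: header `unit,time_samples`
# ---------------------------------------------------------------------------

def save_events(events: Sequence[SpikeEvents], csv_path) -> None:
    frames = [
        pd.DataFrame({"unit": ev.channel, "time_samples": ev.times}) for ev in events
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit", "time_samples"])
    )
    df.to_csv(csv_path, index=False)


def load_events(csv_path, rate: Optional[float] = None) -> list[SpikeEvents]:
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    df.columns = [c.strip() for c in df.columns]
    if not {"unit", "time_samples"} <= set(df.columns):
        raise FormatError("events CSV must have columns unit,time_samples")
    for col in ("unit", "time_samples"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        else:
            continue
        raise FormatError(f"non-numeric value in column '{col}' at line {line}")
    times_all = df["time_samples"].to_numpy()
    if np.any(times_all < 0):
        raise ValidationError("spike times must be non-negative")
    out: list[SpikeEvents] = []
    for unit, grp in df.groupby("unit", sort=True):
        times = np.sort(grp["time_samples"].to_numpy(dtype=np.int64))
        uniq = np.unique(times)
        if uniq.size < times.size:
            warnings.warn(
                f"channel {unit}: collapsed {times.size - uniq.size} duplicate "
                "spike times",
                stacklevel=2,
            )
        out.append(SpikeEvents(channel=int(unit), times=uniq, rate=rate))
    return out


# ---------------------------------------------------------------------------
# WaveformSet I/O: flat binary matrix + JSON sidecar
# ---------------------------------------------------------------------------

def save_waveforms(ws: WaveformSet, binary_path, sidecar_path=None) -> None:
    binary_path = Path(binary_path)
    if sidecar_path is None:
        sidecar_path = binary_path.with_suffix(".json")
    ws.waves.astype(_DTYPE).tofile(binary_path)
    meta = {
        "n_spikes": ws.n_spikes,
        "width": ws.waves.shape[1],
        "n_points": ws.n_points,
        "align_index": ws.align_index,
        "dtype": "<f4",
    }
    if ws.channel_order is not None:
        meta["channel_order"] = list(map(int, ws.channel_order))
    if ws.events is not None:
        meta["events"] = {
            "channel": ws.events.channel,
            "times": ws.events.times.tolist(),
            "rate": ws.events.rate,
        }
    Path(sidecar_path).write_text(json.dumps(meta))


def load_waveforms(binary_path, sidecar_path=None) -> WaveformSet:
    binary_path = Path(binary_path)
    if sidecar_path is None:
        sidecar_path = binary_path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise ConfigError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    raw = np.fromfile(binary_path, dtype=np.dtype(meta.get("dtype", "<f4")))
    width = int(meta["width"])
    if raw.size % width != 0:
        raise FormatError(f"binary of {raw.size} values not divisible by width {width}")
    events = None
    if meta.get("events") is not None:
        ev = meta["events"]
        events = SpikeEvents(
            channel=int(ev["channel"]),
            times=np.asarray(ev["times"], dtype=np.int64),
            rate=ev.get("rate"),
        )
    return WaveformSet(
        waves=raw.reshape(-1, width),
        n_points=int(meta["n_points"]),
        align_index=int(meta["align_index"]),
        events=events,
        channel_order=meta.get("channel_order"),
    )


# ---------------------------------------------------------------------------
# GroundTruth I/O: JSON
# ---------------------------------------------------------------------------

def save_ground_truth(gt: GroundTruth, json_path) -> None:
    doc = {
        "templates": gt.templates.tolist(),
        "units": [
            {
                "unit_id": u.unit_id,
                "times": u.times.tolist(),
                "scales": u.scales.tolist(),
                "template_id": u.template_id,
                "shapes": None if u.shapes is None else u.shapes.tolist(),
            }
            for u in gt.units
        ],
    }
    Path(json_path).write_text(json.dumps(doc))


def load_ground_truth(json_path) -> GroundTruth:
    doc = json.loads(Path(json_path).read_text())
    units = [
        GroundTruthUnit(
            unit_id=int(u["unit_id"]),
            times=np.asarray(u["times"], dtype=np.int64),
            scales=np.asarray(u["scales"], dtype=np.float64),
            template_id=int(u["template_id"]),
            shapes=None if u.get("shapes") is None else np.asarray(u["shapes"]),
        )
        for u in doc["units"]
    ]
    return GroundTruth(units=units, templates=np.asarray(doc["templates"]))


def save_labels(labeling: Labeling, csv_path) -> None:
    pd.DataFrame(
        {"spike_index": np.arange(len(labeling)), "label": labeling.labels}
    ).to_csv(csv_path, index=False)


def load_labels(csv_path, method: str = "") -> Labeling:
    df = pd.read_csv(csv_path)
    df = df.sort_values("spike_index")
    return Labeling(labels=df["label"].to_numpy(dtype=np.int64), method=method)
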