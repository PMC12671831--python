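"""Synthetic extracellular recording generator with exact ground truth.

The generator reproduces the construction used by classic synthetic
spike-sorting benchmarks: peak-normalized spike templates are superposed
at known spike times on top of *structured* background noise, itself made
of randomly placed spike templates and rescaled so that its standard
deviation equals a relative level ``eta`` (in template-peak units).
Defaults: 24 kHz sampling, 64-sample spikes, constant 20 Hz trains.

Perturbation models:

* ``dilution`` — each spike of a unit kept independently with a given
  probability (emulates low-firing "silent" neurons);
* ``bursting`` — each spike replaced by a triplet with decaying amplitudes
  (1.0, 0.7, 0.5) and intra-burst ISIs drawn Normal(3, 1) ms clipped to
  [1, 5] ms;
* ``amp_drift`` — amplitude decreases linearly from 1.0 at the start of
  the recording to 0.3 at the end;
* ``amp_jitter`` — i.i.d. amplitude scale Uniform(0.5, 1.0);
* ``shape_morph`` — spike k is rendered as (1 - a_k) T1 + a_k T2 with the
  morphing factor a_k increasing linearly 0 -> 1 over the spike sequence
  (electrode-drift analogue).

A multielectrode variant attenuates each unit's amplitude on channel c by
``exp(-d(c, unit) / lambda_space)`` with an exponential length constant in
micrometres, and adds independent background noise per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GenerationError, ParameterError, ValidationError
from .io import Geometry, GroundTruth, GroundTruthUnit, Recording

DEFAULT_RATE_HZ = 24000.0
DEFAULT_N_POINTS = 64


def canonical_trough_index(n_points: int) -> int:
    """Trough index mirroring the 30-pre / 30-post snippet convention."""
    return round(n_points * 30 / 61)


@dataclass
class PerturbationSpec:
    """One perturbation applied to one unit's spike train."""

    kind: str  # dilution | bursting | amp_drift | amp_jitter | shape_morph
    unit: int = 0
    fraction: float = 1.0  # dilution keep-probability
    burst_amplitudes: tuple[float, ...] = (1.0, 0.7, 0.5)
    burst_isi_mean_ms: float = 3.0
    burst_isi_sd_ms: float = 1.0
    burst_isi_clip_ms: tuple[float, float] = (1.0, 5.0)
    drift_endpoints: tuple[float, float] = (1.0, 0.3)
    jitter_range: tuple[float, float] = (0.5, 1.0)
    morph_templates: Optional[tuple[int, int]] = None  # (T1 id, T2 id)

    _KINDS = ("dilution", "bursting", "amp_drift", "amp_jitter", "shape_morph")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown perturbation kind {self.kind!r}")
        if not 0 < self.fraction <= 1:
            raise ValidationError("dilution fraction must lie in (0, 1]")
        lo, hi = self.jitter_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("jitter bounds must lie within (0, 1]")
        amps = self.burst_amplitudes
        if any(a <= 0 for a in amps) or any(
            a2 >= a1 for a1, a2 in zip(amps, amps[1:])
        ):
            raise ValidationError("burst amplitudes must be positive decreasing")


@dataclass
class SynthSpec:
    """Study conditions for a single-channel synthetic recording."""

    n_units: int = 3
    rate_hz: float = 20.0  # per-unit firing rate
    duration_s: float = 60.0
    eta: float = 0.1  # background SD relative to template peak (=1)
    rate: float = DEFAULT_RATE_HZ  # sampling Hz
    n_points: int = DEFAULT_N_POINTS
    train_mode: str = "constant"  # constant | poisson
    refractory_ms: float = 2.0
    perturbations: list[PerturbationSpec] = field(default_factory=list)
    noise_kind: str = "colored"  # colored (superposed templates) | white
    n_background_templates: int = 20
    background_rate_hz: float = 50.0  # Poisson density per background template
    background_amp_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValidationError("eta must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.rate <= 0 or self.rate_hz <= 0:
            raise ValidationError("rates must be positive")


@dataclass
class MEASpec(SynthSpec):
    """Multielectrode extension: square grid, per-unit position, attenuation."""

    grid_shape: tuple[int, int] = (5, 5)
    pitch_um: float = 16.0
    neuron_positions_um: Optional[list[tuple[float, float]]] = None
    lambda_space_um: float = 27.0
    shared_noise_fraction: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.lambda_space_um <= 0:
            raise ValidationError("lambda_space_um must be positive")
        if self.neuron_positions_um is not None:
            pos = np.asarray(self.neuron_positions_um, dtype=float)
            if not np.all(np.isfinite(pos)):
                raise ValidationError("neuron positions must be finite")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _biphasic(
    x: np.ndarray,
    trough: float,
    w_neg: float,
    amp_pos: float,
    lag_pos: float,
    w_pos: float,
    amp_pre: float,
    lag_pre: float,
    w_pre: float,
) -> np.ndarray:
    """Smooth spike prototype: dominant negative lobe + after/pre positive lobes."""
    y = -np.exp(-0.5 * ((x - trough) / w_neg) ** 2)
    y += amp_pos * np.exp(-0.5 * ((x - trough - lag_pos) / w_pos) ** 2)
    y += amp_pre * np.exp(-0.5 * ((x - trough + lag_pre) / w_pre) ** 2)
    return y


def generate_templates(
    n_units: int,
    n_points: int = DEFAULT_N_POINTS,
    seed: int = 0,
    max_correlation: float = 0.9,
    max_retries: int = 500,
) -> np.ndarray:
    """Randomized smooth biphasic templates, peak-normalized to exactly 1.

    Each template has its trough (the absolute extremum) at the canonical
    alignment index. The default pairwise-correlation cap of 0.9 keeps the
    spike classes as distinct as the real mean-waveform libraries the
    benchmark construction emulates; near-duplicate templates would make
    the set degenerate rather than hard.
    """
    if n_units < 1:
        raise ParameterError("n_units must be >= 1")
    if n_points < 16:
        raise ParameterError("n_points must be >= 16")
    rng = np.random.default_rng(seed)
    trough = canonical_trough_index(n_points)
    x = np.arange(n_points, dtype=float)
    templates: list[np.ndarray] = []
    attempts = 0
    while len(templates) < n_units:
        if attempts > max_retries * n_units:
            raise GenerationError(
                "could not generate templates satisfying the correlation bound"
            )
        attempts += 1
        t = _biphasic(
            x,
            trough=float(trough),
            w_neg=rng.uniform(1.0, 4.5),
            amp_pos=rng.uniform(0.2, 0.75),
            lag_pos=rng.uniform(2.5, 12.0),
            w_pos=rng.uniform(1.5, 8.0),
            amp_pre=rng.uniform(0.0, 0.45),
            lag_pre=rng.uniform(2.5, 10.0),
            w_pre=rng.uniform(1.5, 6.0),
        )
        t = t / np.max(np.abs(t))
        if np.argmin(t) != trough or abs(t[trough] + 1.0) > 1e-12:
            continue  # positive lobe took over the extremum; redraw
        if any(
            abs(np.corrcoef(t, prev)[0, 1]) >= max_correlation for prev in templates
        ):
            continue
        templates.append(t)
    return np.asarray(templates)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def generate_spike_train(
    rate_hz: float,
    duration_s: float,
    fs: float = DEFAULT_RATE_HZ,
    mode: str = "constant",
    refractory_ms: float = 0.0,
    seed: int = 0,
    phase_s: Optional[float] = None,
) -> np.ndarray:
    """Spike times (integer samples) in [0, duration).

    ``constant`` mode yields equally spaced ISIs of 1/rate with a random
    phase offset (or the given ``phase_s``); ``poisson`` draws exponential
    ISIs, redrawing any ISI shorter than the refractory period.
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ParameterError("rate and duration must be positive")
    if mode == "poisson" and rate_hz * refractory_ms >= 1000:
        raise ParameterError("rate too high for the requested refractory period")
    rng = np.random.default_rng(seed)
    if mode == "constant":
        isi = 1.0 / rate_hz
        phase = rng.uniform(0.0, isi) if phase_s is None else phase_s % isi
        times_s = np.arange(phase, duration_s, isi)
    elif mode == "poisson":
        refr = refractory_ms / 1000.0
        times = []
        t = float(rng.exponential(1.0 / rate_hz))
        while t < duration_s:
            times.append(t)
            isi = float(rng.exponential(1.0 / rate_hz))
            while isi < refr:
                isi = float(rng.exponential(1.0 / rate_hz))
            t += isi
        times_s = np.asarray(times)
    else:
        raise ParameterError(f"unknown train mode {mode!r}")
    samples = np.unique(np.floor(times_s * fs).astype(np.int64))
    return samples[samples < int(round(duration_s * fs))]


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(
    unit: GroundTruthUnit,
    spec: PerturbationSpec,
    templates: np.ndarray,
    fs: float,
    duration_s: float,
    seed: int = 0,
) -> GroundTruthUnit:
    """Return a new unit with the perturbation applied (input untouched)."""
    rng = np.random.default_rng(seed)
    times, scales = unit.times.copy(), unit.scales.copy()
    shapes = None if unit.shapes is None else unit.shapes.copy()

    if spec.kind == "dilution":
        keep = rng.random(times.size) < spec.fraction
        times, scales = times[keep], scales[keep]
        if shapes is not None:
            shapes = shapes[keep]
    elif spec.kind == "bursting":
        amps = np.asarray(spec.burst_amplitudes)
        new_times, new_scales = [], []
        for t, s in zip(times, scales):
            tt = float(t)
            for j, a in enumerate(amps):
                if j > 0:
                    isi_ms = float(
                        np.clip(
                            rng.normal(spec.burst_isi_mean_ms, spec.burst_isi_sd_ms),
                            *spec.burst_isi_clip_ms,
                        )
                    )
                    tt += isi_ms / 1000.0 * fs
                new_times.append(int(round(tt)))
                new_scales.append(s * a)
        order = np.argsort(new_times, kind="stable")
        t_arr = np.asarray(new_times)[order]
        s_arr = np.asarray(new_scales)[order]
        # collisions at the same sample are vanishingly rare; nudge forward
        for i in range(1, t_arr.size):
            if t_arr[i] <= t_arr[i - 1]:
                t_arr[i] = t_arr[i - 1] + 1
        times, scales, shapes = t_arr, s_arr, None
    elif spec.kind == "amp_drift":
        a0, a1 = spec.drift_endpoints
        frac = times / max(duration_s * fs - 1, 1)
        scales = scales * (a0 + (a1 - a0) * frac)
    elif spec.kind == "amp_jitter":
        scales = scales * rng.uniform(*spec.jitter_range, size=times.size)
    elif spec.kind == "shape_morph":
        if spec.morph_templates is None:
            raise ParameterError("shape_morph requires morph_templates=(T1, T2)")
        t1 = templates[spec.morph_templates[0]]
        t2 = templates[spec.morph_templates[1]]
        if t1.shape != t2.shape:
            raise ParameterError("morph templates must have equal length")
        n = times.size
        alpha = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
        shapes = (1 - alpha)[:, None] * t1[None, :] + alpha[:, None] * t2[None, :]
    keep = times < int(round(duration_s * fs))
    if not np.all(keep):
        times, scales = times[keep], scales[keep]
        if shapes is not None:
            shapes = shapes[keep]
    return GroundTruthUnit(
        unit_id=unit.unit_id,
        times=times,
        scales=scales,
        template_id=unit.template_id,
        shapes=shapes,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_spikes(
    trace: np.ndarray,
    times: np.ndarray,
    scales: np.ndarray,
    shapes: np.ndarray,
    trough_index: int,
) -> None:
    """Superpose scale * shape at each spike time (trough lands on the time)."""
    times = np.asarray(times, dtype=np.int64)
    if times.size == 0:
        return
    shapes = np.atleast_2d(np.asarray(shapes, dtype=np.float64))
    n_points = shapes.shape[1]
    if shapes.shape[0] == 1:
        shapes = np.broadcast_to(shapes, (times.size, n_points))
    idx = times[:, None] + np.arange(n_points)[None, :] - trough_index
    vals = np.asarray(scales, dtype=np.float64)[:, None] * shapes
    ok = (idx >= 0) & (idx < trace.size)
    np.add.at(trace, idx[ok], vals[ok])


def _background(
    n_samples: int,
    fs: float,
    eta: float,
    spec: SynthSpec,
    trough_index: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if eta == 0:
        return np.zeros(n_samples)
    if spec.noise_kind == "white":
        return eta * rng.standard_normal(n_samples)
    bg_templates = generate_templates(
        spec.n_background_templates,
        spec.n_points,
        seed=int(rng.integers(2**31)),
    )
    duration_s = n_samples / fs
    noise = np.zeros(n_samples)
    total_rate = spec.background_rate_hz * spec.n_background_templates
    n_events = rng.poisson(total_rate * duration_s)
    times = rng.integers(0, n_samples, size=n_events)
    which = rng.integers(0, spec.n_background_templates, size=n_events)
    amps = rng.uniform(*spec.background_amp_range, size=n_events)
    _add_spikes(noise, times, amps, bg_templates[which], trough_index)
    sd = noise.std()
    if sd > 0:
        noise *= eta / sd
    return noise


def _build_units(spec: SynthSpec, rng: np.random.Generator) -> tuple[list[GroundTruthUnit], np.ndarray]:
    templates = generate_templates(
        spec.n_units, spec.n_points, seed=int(rng.integers(2**31))
    )
    units = []
    for u in range(spec.n_units):
        # constant-mode phases are stratified across units: with exactly
        # equal rates an unconstrained phase draw would, with positive
        # probability, lock two units into overlapping on *every* spike
        # for the whole recording, a degenerate configuration real
        # (non-phase-locked) neurons do not produce
        phase = None
        if spec.train_mode == "constant":
            isi = 1.0 / spec.rate_hz
            phase = isi * (u + rng.uniform(0.15, 0.85)) / spec.n_units
        times = generate_spike_train(
            spec.rate_hz,
            spec.duration_s,
            fs=spec.rate,
            mode=spec.train_mode,
            refractory_ms=spec.refractory_ms,
            seed=int(rng.integers(2**31)),
            phase_s=phase,
        )
        units.append(
            GroundTruthUnit(
                unit_id=u,
                times=times,
                scales=np.ones(times.size),
                template_id=u,
            )
        )
    for pert in spec.perturbations:
        units[pert.unit] = apply_perturbation(
            units[pert.unit],
            pert,
            templates,
            fs=spec.rate,
            duration_s=spec.duration_s,
            seed=int(rng.integers(2**31)),
        )
    return units, templates


def render_recording(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Render a single-channel recording plus exact ground truth."""
    n_samples = int(round(spec.duration_s * spec.rate))
    if n_samples < spec.n_points:
        raise ParameterError("duration shorter than one spike window")
    rng = np.random.default_rng(spec.seed)
    units, templates = _build_units(spec, rng)
    trough = canonical_trough_index(spec.n_points)
    trace = np.zeros(n_samples)
    for u in units:
        shapes = u.shapes if u.shapes is not None else templates[u.template_id]
        _add_spikes(trace, u.times, u.scales, np.asarray(shapes), trough)
    trace += _background(n_samples, spec.rate, spec.eta, spec, trough, rng)
    rec = Recording(samples=trace[None, :], rate=spec.rate)
    return rec, GroundTruth(units=units, templates=templates)


def mea_geometry(spec: MEASpec) -> Geometry:
    ni, nj = spec.grid_shape
    coords = [(i, j) for i in range(ni) for j in range(nj)]
    return Geometry(coords=coords, pitch_um=spec.pitch_um)


def render_mea(spec: MEASpec) -> tuple[Recording, GroundTruth]:
    """Render a multielectrode recording with exponential spatial attenuation.

    Channel c sees each unit's spikes scaled by exp(-d(c, unit)/lambda);
    background noise is drawn independently per channel at level eta, with
    an optional fraction shared across channels. All channels share the
    ground-truth spike times.
    """
    n_samples = int(round(spec.duration_s * spec.rate))
    if n_samples < spec.n_points:
        raise ParameterError("duration shorter than one spike window")
    rng = np.random.default_rng(spec.seed)
    units, templates = _build_units(spec, rng)
    geom = mea_geometry(spec)
    positions = geom.positions_um()
    if spec.neuron_positions_um is None:
        # default: units at the central electrode
        center = positions.mean(axis=0)
        ci = int(np.argmin(np.linalg.norm(positions - center, axis=1)))
        neuron_pos = np.tile(positions[ci], (spec.n_units, 1))
    else:
        neuron_pos = np.asarray(spec.neuron_positions_um, dtype=float)
        if neuron_pos.shape[0] != spec.n_units:
            raise ValidationError("need one position per unit")
    trough = canonical_trough_index(spec.n_points)
    n_channels = positions.shape[0]
    samples = np.zeros((n_channels, n_samples), dtype=np.float64)
    shared = (
        _background(n_samples, spec.rate, spec.eta, spec, trough, rng)
        if spec.shared_noise_fraction > 0
        else 0.0
    )
    for c in range(n_channels):
        for u in units:
            d = float(np.linalg.norm(positions[c] - neuron_pos[u.unit_id]))
            atten = np.exp(-d / spec.lambda_space_um)
            shapes = u.shapes if u.shapes is not None else templates[u.template_id]
            _add_spikes(samples[c], u.times, u.scales * atten, np.asarray(shapes), trough)
        own = _background(n_samples, spec.rate, spec.eta, spec, trough, rng)
        f = spec.shared_noise_fraction
        samples[c] += np.sqrt(1 - f**2) * own + f * shared
    rec = Recording(samples=samples, rate=spec.rate, geometry=geom)
    return rec, GroundTruth(units=units, templates=templates)
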