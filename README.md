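# umapsort

Spike sorting — assigning detected extracellular action potentials to the
neurons that fired them — hinges on the dimensionality reduction applied to
spike waveforms before clustering. `umapsort` implements a threshold-based
sorting pipeline whose reduction step is **UMAP** (nonlinear,
topology-preserving) clustered by **HDBSCAN** (density-based, infers the
cluster count, labels outliers as noise), together with the classical
**PCA** and **wavelet** baselines, so the three feature spaces can be
compared under identical conditions.

The package is aimed at electrophysiologists and methods researchers who
want a fully testable sorting pipeline: every stage can be exercised on
synthetic recordings with exact ground truth, so claims about sorting
quality are measurable rather than anecdotal.

It provides:

- **Synthetic benchmark generator** (`umapsort.synth`) — peak-normalized
  spike templates superposed at known times over *structured* background
  noise (random spike waveforms rescaled to a relative level η), with
  perturbation models for dilution (low-firing "silent" neurons), bursting
  (amplitude triplets 1.0/0.7/0.5, ~3 ms intra-burst ISIs), linear
  amplitude drift (1.0 → 0.3), amplitude jitter (Uniform(0.5, 1)), and
  waveform morphing S_k = (1 − α_k)·T1 + α_k·T2. A multielectrode variant
  attenuates amplitudes as exp(−d/λ) across a grid of electrodes.
- **Preprocessing** (`umapsort.preprocess`) — zero-phase 500–2000 Hz
  band-pass, robust threshold detection (σ = median(|x|)/0.6745), 61-sample
  snippet extraction (30 pre- / 30 post-trough), and waveform conditioning:
  Savitzky–Golay smoothing → PCHIP interpolation → sub-sample trough
  alignment → decimation.
- **Feature extraction** (`umapsort.features`) — scikit-learn style
  transformers `UMAPEmbedder` (n_components=2, min_dist=0, n_neighbors=15),
  `PCAEmbedder` (eigendecomposition of the waveform covariance), and
  `WaveletEmbedder` (multilevel DWT with Kolmogorov–Smirnov ranking of
  coefficients, top-K selection), plus KS-divergence-based neighborhood
  tuning.
- **Clustering** (`umapsort.cluster`) — HDBSCAN plus K-means / Gaussian
  mixture baselines, and ground-truth-matched best-unit selection.
- **Evaluation** (`umapsort.evaluate`) — one-to-one spike matching within a
  tolerance ε, precision P = TP/(TP+FP), recall R = TP/(TP+FN),
  F1 = 2PR/(P+R), and the inclusion-index matrix I_{i,j} (percentage of
  spikes of train i present in train j; with a ground-truth train, its row
  and column are recall and precision).
- **Multielectrode analysis** (`umapsort.multichannel`) — hotspot
  selection, super-waveform concatenation across electrodes, concentric
  ring (cumulative) geometric analysis, per-electrode spatial F1 maps, and
  exponential decay fits F1(x) = A·e^(−x/τ) + B.
- **Encoding analysis** (`umapsort.info`) — causal windowed firing rates
  (200 ms windows, 20 ms steps) and plug-in mutual information
  I(r; s) = Σ_i Σ_k P(r_i|s_k) P(s_k) log₂(P(r_i|s_k)/P(r_i)) with
  permutation significance, permutation-mean bias correction, and
  cluster-size multiple-comparison correction.

## Worked example

Sort a synthetic recording of three 20 Hz units at noise level η = 0.05
and score each ground-truth unit's best-matching cluster:

```python
import numpy as np
from umapsort import (
    SynthSpec, render_recording, PipelineConfig, sort_recording,
    select_best_unit,
)

spec = SynthSpec(n_units=3, rate_hz=20.0, duration_s=30.0, eta=0.05, seed=0)
recording, truth = render_recording(spec)
gt_times = np.sort(np.concatenate([u.times for u in truth.units]))

config = PipelineConfig(method="umap", seed=0, use_gt_times=True)
result = sort_recording(recording, config, gt_times=gt_times)
print(f"clusters found: {result.labeling.cluster_ids.size}, "
      f"noise fraction: {result.labeling.noise_fraction:.1%}")
for unit in truth.units:
    label, m = select_best_unit(result.labeling, result.events.times,
                                unit.times, epsilon=12)
    print(f"unit {unit.unit_id}: cluster {label}, precision {m.precision:.3f}, "
          f"recall {m.recall:.3f}, F1 {m.f1:.3f}")
```

Output:

```
clusters found: 3, noise fraction: 0.0%
unit 0: cluster 1, precision 1.000, recall 1.000, F1 1.000
unit 1: cluster 0, precision 1.000, recall 1.000, F1 1.000
unit 2: cluster 2, precision 1.000, recall 1.000, F1 1.000
```

Each of the three units is recovered as its own cluster with no
contamination (precision 1) and no lost spikes (recall 1); ε = 12 samples
is 0.5 ms at the 24 kHz sampling rate. Swapping `method="pca"` or
`"wavelet"` reruns the identical pipeline with a different feature space —
on harder conditions (higher η, diluted units) their F1 drops below
UMAP's; see `umapsort.pipeline.run_benchmark` for full sweeps.

A `umapsort` command-line interface wraps the same stages
(`umapsort synth | detect | waveforms | embed | cluster | eval |
inclusion | sort | benchmark | mea-map | mea-geometric | info`).

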