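# Methods

## Pipeline

The sorter follows the classical threshold-based chain:

1. **Band-pass filter** — 4th-order Butterworth, 500–2000 Hz, applied
   forward-backward (zero phase) per channel so trough timing is
   preserved. The band isolates the spectral content of extracellular
   spikes; the mean is removed first.
2. **Detection** — robust noise scale σ = median(|x|)/0.6745 (median-based
   so that spikes themselves do not inflate the threshold), threshold
   k·σ with k = 4 on negative deflections by default. Supra-threshold
   regions are reduced to their extremum sample; events closer than a
   1 ms dead time are merged keeping the deeper trough. On a noiseless
   trace σ is 0 and any deflection of the configured polarity counts,
   so ground-truth recovery is exact in the η = 0 limit.
3. **Windowing** — inclusive snippets [t − 30, t + 30] (61 samples at
   24 kHz, ~2.5 ms) around each event; 0-based sample indexing
   throughout, times stored as integer sample indices.
4. **Conditioning** — per row: Savitzky–Golay smoothing (order 3, window
   5 samples), PCHIP interpolation onto a 4× finer grid, a shift placing
   the trough at the alignment index, decimation back to 61 samples.
5. **Embedding** — UMAP with n_components = 2, min_dist = 0,
   n_neighbors = 15 and a fixed seed (delegated to umap-learn); or the
   PCA / wavelet baselines.
6. **Clustering** — HDBSCAN (scikit-learn implementation) with
   min_cluster_size = 25; noise label −1. K-means and Gaussian-mixture
   baselines assign every point.
7. **Scoring** — one-to-one spike matching within ε (default 0.5 ms =
   12 samples at 24 kHz), precision/recall/F1, inclusion matrices.

### Trough alignment

The conditioning step estimates each snippet's trough location by a
least-squares parabola over the 7 samples around the discrete minimum of
the smoothed row, then shifts on the fine grid so that location lands on
the alignment index. Using the single deepest interpolated sample instead
is numerically fragile: PCHIP minima sit at knots, so when a flat trough
straddles two samples, measurement noise flips the estimate by a whole
sample and splits one unit's waveforms into two artificial shape modes.
The parabola averages the noise over its support and yields an unbiased,
unimodal sub-sample estimate (jitter SD ≈ 0.1–0.2 samples on the synthetic
benchmark).

For concatenated multielectrode "super-waveforms" the shift is computed
once per spike from the reference (hotspot) channel's block and applied to
every block, keeping the channels time-locked; aligning each block
independently — or on the first block, which may be a far, noise-dominated
electrode — would destroy the spatial pattern.

### Matching

Matching is one-to-one: each ground-truth spike takes the earliest
still-unmatched sorted spike within ε, sweeping both trains in time
order. This greedy rule attains the maximum possible number of matches
(exchange argument on sorted trains; the test suite verifies equality
with an optimal-assignment oracle on random instances) and prevents a
burst triplet from matching one ground-truth spike three times.

## Synthetic benchmark generator

The generator emulates the standard synthetic extracellular benchmark
construction: spike templates with peak amplitude normalized to exactly
1, superposed at known times, over structured background noise.

- **Templates** are smooth biphasic shapes (a dominant negative Gaussian
  lobe plus randomized positive lobes before/after), trough fixed at the
  canonical index ⌊64·30/61⌉, drawn until all pairwise Pearson
  correlations fall below 0.9. Real mean-waveform libraries contain
  clearly distinct spike classes; without the cap, two random draws can
  be near-duplicates (r > 0.95), which makes the task degenerate rather
  than hard.
- **Spike trains** default to a constant 20 Hz rate with a random phase,
  at 24 kHz sampling and 64-sample spikes. Phases are stratified across
  units: with exactly equal constant rates, independent phases would —
  with probability ≈ 5% per pair — lock two units into overlapping on
  *every* spike for the entire recording, a configuration real,
  non-phase-locked neurons do not produce. Stratification preserves each
  train's marginal statistics while bounding pairwise phase collisions.
  A Poisson mode with a refractory period is also provided.
- **Background noise** is "colored": spikelets drawn from a separate pool
  of 20 background templates are placed at Poisson times (50 Hz per
  template) with Uniform(0.5, 1.0) amplitudes, then the whole background
  is rescaled so its standard deviation equals η in template-peak units.
  η is therefore the noise SD relative to spike amplitude. A white-noise
  option exists for ablation. The spikelet amplitude distribution and
  placement density are free choices (only the post-rescaling SD is
  specified by the construction); both are configurable.
- **Perturbations**: dilution keeps each spike independently with
  probability f; bursting replaces each spike by a triplet with scales
  (1.0, 0.7, 0.5) and intra-burst ISIs ~ Normal(3, 1) ms clipped to
  [1, 5] ms; amplitude drift scales linearly from 1.0 at the start to
  0.3 at the end; amplitude jitter draws i.i.d. Uniform(0.5, 1.0);
  shape morphing renders spike k as (1 − α_k)T1 + α_k T2 with α_k linear
  from 0 to 1 over the spike sequence.
- **Multielectrode variant**: a square grid (default 5×5, 16 µm pitch);
  channel c sees each unit scaled by exp(−d(c, unit)/λ) with λ in µm
  (default 27 µm), independent background per channel at level η with an
  optional shared fraction. All channels share the ground-truth times.

When scoring the synthetic benchmark, waveforms are extracted at the
known ground-truth spike times (`use_gt_times`), so the F1 scores isolate
the feature-extraction and clustering stages; threshold detection is
exercised separately (its recall/false-alarm contracts, and the
multielectrode analysis, which always detects on the hotspot).

What the generator does **not** emulate: electrode drift as geometry
change (drift is modeled as waveform morphing), biophysical membrane
dynamics, spatially correlated noise beyond the optional shared fraction,
and overlapping-spike resolution. Passing benchmarks here therefore
demonstrates correctness of the pipeline and its relative method
ordering under controlled conditions, not absolute performance on any
particular real preparation.

## Multielectrode analysis

The *hotspot* is the channel maximizing the mean trough depth of
time-locked snippets (ties to the lowest index). Concentric "rings" on
the square grid are Chebyshev shells (ring r = channels at max(|Δi|,|Δj|)
= r) — sizes 1, 8, 16 on a 5×5 patch — while the F1-vs-distance profile
uses Euclidean distances in µm. Cumulative geometric analysis
concatenates snippets over rings 0..r (channels canonicalized row-major;
the hotspot's detected events are the temporal reference) and reruns
embedding + clustering per step; a "full MEA" variant concatenates all
channels at once. Per-electrode maps rerun the complete single-channel
pipeline independently with seed = base + channel index. The spatial
decay of F1 is fit as F1(x) = A·e^(−x/τ) + B by bounded nonlinear least
squares (A ∈ [0, 1.5], τ ∈ (0, 10³] µm, B ∈ [0, 1]) with four τ starts
spanning the distance range; flat profiles (variance < 10⁻⁶) raise a
degenerate-fit error rather than returning a meaningless τ.

## Mutual information

Firing rates use rectangular causal windows (200 ms length, 20 ms step):
the rate stamped at time t counts spikes in (t − 0.2 s, t]. Rates at each
bin are discretized into quantile bins (default 8; quantiles keep P(r)
non-degenerate for low-rate units) and plugged into

I(r; s) = Σ_i Σ_k P(r_i | s_k) P(s_k) log₂( P(r_i | s_k) / P(r_i) )

with 0·log 0 = 0 and P(r) pooled across conditions. Significance uses a
permutation null: condition labels are shuffled across trials, the same
shuffles reused for every time bin within a draw;
p = (1 + #{perm ≥ observed})/(n_perm + 1). The finite-sampling bias of
the plug-in estimator is corrected by subtracting the permutation-mean
MI — the permutation machinery is already required, and its mean equals
the null bias to first order, (N_r − 1)(M − 1)/(2n·ln 2) bits. Multiple
comparisons across bins are handled by keeping only runs of ≥ 5
consecutive significant bins (100 ms at the 20 ms step).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| band | 500–2000 | Hz | spike-band isolation; zero-phase to keep trough timing |
| k_sigma | 4 | — | standard robust threshold multiplier; configurable |
| dead time | 1 | ms | merges multi-lobe crossings of one spike |
| pre/post | 30/30 | samples | 61-sample snippets at 24 kHz (~2.5 ms) |
| sg_order / sg_window | 3 / 5 | — / samples | smooths noise, preserves cubic spike shape exactly |
| upsample_factor | 4 | — | quarter-sample alignment; finer grids change < 0.1% RMS |
| n_neighbors / min_dist | 15 / 0 | — | UMAP sorting defaults; min_dist 0 keeps density structure |
| min_cluster_size | 25 | spikes | above burst-triplet artifacts, below a 60 s × 1 Hz unit |
| ε | 0.5 | ms | 12 samples at 24 kHz; always logged, must be stated with results |
| n_rate_bins | 8 | — | quantile bins; trades resolution against plug-in bias |
| n_perm / α | 1000 / 0.05 | — | permutation null; cluster_min_bins = 5 bins (100 ms) |

## Problem sizes

The test suite and the acceptance script run the benchmark at 30–60 s
recordings (600–1200 spikes per unit at 20 Hz), three units, seeds fixed
in advance; the multielectrode analyses use 12–20 s recordings on a 5×5
grid; the permutation-test calibration uses 300–500 simulated null
neurons at 200 permutations. These sizes give stochastic checks
comfortable margins (binomial SE of a rejection-rate estimate at
n ≈ 6000 bins is ≈ 0.3%) while keeping a full run on a single CPU in
minutes.

## Known limitations

- HDBSCAN's excess-of-mass cluster selection excludes the root cluster,
  so a recording containing exactly one unit would come back all-noise;
  the clusterer retries with single-cluster selection enabled when the
  first pass finds nothing.
- UMAP embeddings are deterministic only for a fixed seed *and* a fixed
  umap-learn version; regression values should not be compared across
  dependency upgrades.
- The wavelet baseline follows standard DWT semantics (approximation =
  scaling-function coefficients); sources differ in labeling conventions.
- Overlapping spikes are rendered additively and are not resolved; at
  high rates or high unit counts overlap, not noise, dominates errors.
- Detection-conditional selection bias (noise tipping the extremum
  sample) slightly reshapes near-threshold waveform populations; the
  parabolic alignment removes the resulting bimodality but not the bias
  itself.
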