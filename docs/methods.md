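# Methods

This note documents the models, parameter choices and numerical decisions
behind `cortexdyn`, and what the synthetic-data generators do and do not
emulate.

## Trace model and detection

A session is a 900 s, 10 Hz recording of one field of view. The simulator
assigns each cell a stratum mirroring the four downstream activity
categories, with default weights (silent 0.35, rare 0.323, intermediate
0.325, high 0.002). Within-stratum rates are drawn right-skewed — rare and
high log-uniformly on (0.05, 0.5] and (4, 5] events/min, intermediate from
a truncated exponential with mean 0.7 events/min on (0.5, 4] — so that
most active cells sit at the low rates typical of spontaneous layer-2/3
activity and only a sliver of the population is highly active. Event times
are Poisson; each event adds a difference-of-exponentials kernel
(τ_rise = 0.18 s, τ_decay = 1.8 s, slow-indicator kinetics; the kernel
shape is configurable) with peak amplitude 3.0 ΔF/F over Gaussian noise of
SD 0.1. Neuropil contamination is a shared slow sinusoid-plus-noise per
field of view, injected into each ROI trace with gain 0.7 and removed by
the compensation formula downstream.

Two properties of the detection rule shaped these defaults:

* The threshold is `baseline + 3·SD` of the **entire** normalized trace
  (the literal rule; a noise-only SD is available as `sd_mode="residual"`).
  Because the trace's own transients inflate that SD, the threshold excess
  in kernel units is `3·sqrt(r·∫k²dt)` for event rate r — independent of
  amplitude. With the default kinetics this means isolated unitary events
  become undetectable above ≈2.3 events/min: the supra-threshold run drops
  below the 10-frame minimum. This saturation is inherent to the rule, not
  to the implementation; real recordings escape it because high-rate cells
  produce summating multi-spike bursts. Under the default rate
  distribution the detector achieves event-level sensitivity ≈0.92–0.96
  and epoch-level precision ≈1.0 (500 cells × 15 min per seed), which is
  what the acceptance checks measure.
* Normalization divides by F₀ (median of values strictly below the 70th
  percentile, linear-interpolation percentiles) without subtracting, so
  baseline ≈ 1. An all-constant trace takes F₀ = that constant (logged)
  to keep the degenerate case total. Scaling the input leaves the
  normalized trace unchanged.

Transients are maximal supra-threshold runs with no gap-merging; a run
touching the end of the trace counts if long enough. Note that the epoch
*count* is not monotone in the threshold multiplier (raising the threshold
can split an epoch); total supra-threshold time is, and that is the
invariant the property tests assert.

## Activity metrics

Category boundaries make a partition with inclusive upper bounds: rare =
(0, 0.5], intermediate = (0.5, 4], high = (4, ∞) transients/min. The
reoccurrence rate at session s is the fraction of reference-session-active
cells active in *every* session up to s (cumulative intersection), hence
monotone non-increasing from 1. Stationary-epoch frequencies attribute a
transient to the stationary state by its onset frame (the rule for
transients spanning state changes is otherwise undefined) and rescale by
stationary minutes — the only self-consistent rate. The stationary speed
threshold defaults to 0 (synthetic speed is exactly zero at rest);
sessions under 1% stationary time are flagged and excluded, not errors.

## Synchrony

The binarization low-pass is realized as a second-order zero-phase
(forward–backward) Butterworth at 0.3 Hz; smoothing is a 4-frame boxcar
(`same` convolution, so edges carry a half-window offset). The "noise band"
is estimated as the SD of (original − low-passed) residuals; the SD of
sub-median values is available as an alternative. Shuffle offsets are
drawn per cell, in cell order, from one seeded stream, uniformly on
{1, …, n_frames − 1} (zero excluded so every row is displaced); rotation
preserves each row's event count and autocovariance exactly. Pairs
involving a constant row have undefined r and are recorded as missing.

The trace simulator generates cells with *independent* event times (the
only shared component is neuropil, which compensation removes), so
binarized simulated cohorts are expected to sit inside the shuffled null
band. Genuinely synchronous inputs for null-model calibration come from
`simulate_binary_raster`, which plants a shared block-event drive in a
subset of rows (±2 frames jitter).

## Synapse quantification

Components use 8-connectivity (the particle-analysis default); puncta of
≤2 px are excluded. Distances are centroid-to-centroid ("coordinates of
the puncta"); nearest-edge distance is not implemented but the counting
convention is configurable: the default counts presynaptic puncta with at
least one partner within 1 µm (each pre counted once), `mode="pairs"`
counts all qualifying pairs. The perisomatic annulus is the region between
the soma polygon and its outward dilation (default 1.5 µm); marker pixels
count by their centers, so the measure converges with resolution up to
pixel-quantization error. The scene generator keeps paired centroids well
inside the pairing distance (≤0.8×) and all other pre/post centroids
beyond 2×, so rasterization cannot flip a classification and re-measuring
a rendered scene recovers the constructed pairing exactly.

## Proteome statistics

The moderated statistic is d = (mean_b − mean_a)/(se + s0) with pooled
two-sample se and s0 = 0.1. The null uses label permutations: all distinct
assignments when there are ≤ n_perm (identity excluded), otherwise n_perm
distinct random draws. For each protein's |d| threshold the false-positive
estimate is the median permuted exceedance count over the observed count;
q is the minimum estimated FDR over all thresholds that still include the
protein, making q monotone non-increasing in |d|. Missing values are
handled complete-case (no imputation), with dropped counts logged. The
Fisher comparison of down- vs up-regulated proportions is two-sided by
summing hypergeometric outcomes no more likely than the observed table.
PCA centers proteins but does not variance-scale (LFQ intensities share a
scale); the separating component maximizes the standardized between-group
score gap and is oriented so the group of interest scores positively, so
"down" drivers are the most negative loadings regardless of SVD sign.

## Workflow and reproducibility

`run_study` forks one root seed into labelled substreams (wildtype traces,
affected traces, synchrony, proteome), so any stage can be re-run in
isolation from the manifest with identical outputs. The default study —
two cohorts × 150 cells × 4 sessions, 20 shuffle draws on ≤100 cells, and
a 2000-protein differential — completes in well under ten minutes on one
CPU; the acceptance script uses 500-cell cohorts, 3 seeds, 200 shuffle
draws and 20 puncta scenes.

## What the generators do not emulate

* No pixel-level movies: traces are generated at ROI level, so motion
  artifacts, ROI mis-segmentation and spatially varying neuropil are out
  of scope (mask-level rendering exists only for puncta scenes).
* Transients are unitary events of fixed amplitude; real bursts summate
  into larger, longer transients, which is why real high-rate cells remain
  detectable while simulated ones saturate (see above).
* Cells are statistically independent, so simulated cohorts carry no true
  synchrony; synchrony calibration uses the raster generator instead.
* The proteome simulator has Gaussian noise, no missing values and no
  correlation between proteins; FDR calibration under it does not speak to
  missing-value handling on real tables.

Passing tests therefore demonstrate correctness of the implemented rules
and calibration under these idealized conditions, not performance on raw
recordings.
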