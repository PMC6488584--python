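# cortexdyn

Analysis pipeline for longitudinal single-cell calcium-imaging studies of
cortical network dysfunction, with companion statistics for synaptic
histology and quantitative proteomics. It is aimed at labs that follow the
same populations of neurons across repeated awake two-photon imaging
sessions (e.g. in a neurodegeneration model vs. wildtype littermates) and
want a tested, scriptable reimplementation of the standard analysis chain
instead of ad-hoc ImageJ/Matlab macros.

## What it computes

**Trace pipeline.** Per-ROI fluorescence is corrected for neuropil
contamination with a fixed coefficient,

    F_comp = F_ROI − 0.7 · (F_neuropil − median(F_neuropil)),

where the neuropil signal comes from a ring built by fitting the ROI with
an ellipse (second-order image moments), stretching it by 6 px and
removing all labelled ROI pixels. The trace is normalized by
F₀ = median{F < P₇₀(F)} (division, not subtraction, so baseline sits near
1), and a **calcium transient** is a maximal run of the normalized trace
above `baseline + 3·SD` lasting ≥ 10 consecutive frames (1 s at 10 Hz).

**Activity metrics.** For cells reidentified in every session: fraction of
active cells, activity categories — silent (0/min), rarely active
(>0–0.5], intermediately active (>0.5–4], highly active (>4 transients/min)
— with 4×4 transition counts, reoccurrence rate (cells active at a
reference session and in *every* later session), per-cell frequency
changes, and stationary-epoch frequencies (sessions with <1% stationary
time are excluded).

**Synchrony.** Active-cell traces are binarized (zero-phase 0.3 Hz
low-pass, 4-frame smoothing, threshold at 2·SD of the noise band), Pearson
r is computed for every pair over the entire session, and a null is built
by circularly shifting each cell's trace by a random offset — preserving
every per-cell statistic while destroying cross-cell timing.

**Synapse quantification.** Puncta are 8-connected components of binary
marker masks (≤2 px excluded); a putative synapse is a presynaptic punctum
with a postsynaptic centroid within 1 µm. Perisomatic innervation is
marker area in a 1.5 µm annulus around a traced soma, per µm of perimeter;
cell densities are counts per mm² (or mm³).

**Proteome statistics.** On log2 LFQ tables: the s0-moderated statistic
d = Δmean/(se + s0) with s0 = 0.1, permutation-based FDR (q < 5%),
down/up fractions of a protein subset with a two-sided Fisher exact
comparison, and PCA "main drivers" (top-25 loadings on the component
separating a sample group).

**Synthetic data.** Every stage has a seeded generator with ground truth:
GCaMP6s-like traces (Poisson events ⊛ rise/decay kernel + shared neuropil
+ noise), locomotion tracks, rendered pre/post puncta scenes with known
pairing, and two-group LFQ tables with known regulated proteins.

## Worked example

```python
import cortexdyn as cd

cfg = cd.SimulationConfig(n_cells=150, n_sessions=4, affected_fraction=1.0, seed=0)
traces, truth = cd.simulate_traces(cfg)

nt, ts = cd.process_trace(traces[4][0])   # cell 4, session 0
print(ts.count, round(ts.frequency, 2), ts.is_active)
# 18 1.2 True

import numpy as np
change = [cd.process_trace(c[2])[1].frequency - cd.process_trace(c[1])[1].frequency
          for c in traces]
print(round(float(np.median(change)), 2))
# 0.53
```

The first line of output says cell 4 had 18 detected transients in its
first 15-minute session (1.2 transients/min — intermediately active). The
second is the median per-cell frequency change across the simulated effect
onset: every cell gained +0.5 events/min from session 2 onward, and the
detected change recovers it (0.53/min, within the detector's resolution of
1/15 min).

The same study end-to-end, from the shell:

```sh
cortexdyn run --seed 0 --out study_out    # writes CSVs + manifest.json
```

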