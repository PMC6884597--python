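# calcispect

Functional-maturation analysis of spontaneous calcium activity in 3-D
neural cultures — an end-to-end, tested pipeline from raw fluorescence
movies to oscillation statistics, activity clusters and volume-fraction
quantification.

## What it does, and for whom

Long-term 3-D cultures of differentiating human neural stem cells develop
spontaneous calcium dynamics: sparse transients early on, and with
maturation, sustained periodic oscillations (roughly 0.5–3 Hz) in
subpopulations of cells. Quantifying that maturation from wide-field
calcium-indicator movies requires several non-trivial steps, each of which
this package implements as a reusable, composable library:

1. **ROI extraction** — the temporal variance of every pixel is mapped,
   smoothed with a 2-D Gaussian, and local maxima of the variance heatmap
   seed connected regions; each region's single-pixel trace is read at its
   center of mass.
2. **ΔF/F** — `ΔF/F = (F − F₀)/F₀` with `F₀(t)` the mean of the samples
   below the 80th percentile of a ±15 s sliding window, followed by a
   second-order Savitzky–Golay filter.
3. **Oscillation detection** — Welch PSD (8 s windows, 2 s overlap), then
   removal of the aperiodic 1/f component by subtracting a least-squares
   line from log₁₀ PSD vs log₁₀ f over 0.2–8 Hz. Spectral peaks exceeding
   3 SD of the detrended spectrum are pooled across all ROIs, and peaks in
   the top 75% of the pooled height distribution mark significant
   oscillations. Total power in [0.2, 3] Hz quantifies activity strength.
4. **Cluster analysis** — each ROI is summarized by an 8-feature
   time-frequency vector; ROIs form a complete graph weighted by the
   reciprocal L2 distance `w_ij = 1/(d_ij + ε)` between standardized
   vectors; Louvain modularity maximization is repeated 100 times and
   stabilized by co-assignment consensus; separation is scored by Dunn's
   index on a 2-D UMAP embedding.
5. **Volume quantification** — two-channel confocal z-stacks (GFAP /
   β-III tubulin) are binarized and the astrocyte-to-neuron volume ratio
   is the ratio of their foreground voxel fractions.
6. **Synthetic ground truth** — a first-class generator plants
   oscillatory, transient-only and silent units (as traces or rendered
   movies) with machine-readable truth, so every stage is validated by
   recovery of known structure.

It is intended for researchers analyzing slow calcium-indicator recordings
of cultured neural tissue, and for anyone who needs a reference
implementation of variance-map ROI detection, sliding-percentile ΔF/F or
1/f-corrected oscillation calling.

## Worked example

```python
import numpy as np
from calcispect import SimulationConfig, simulate_traces
from calcispect.traces import process_traceset
from calcispect.spectral import analyze_traces, summarize_group

cfg = SimulationConfig(n_rois=40, fraction_oscillatory=0.5,
                       n_frames=1200, rng_seed=12)   # 60 s at 20 Hz
traces, truth = simulate_traces(cfg)
dffs = process_traceset(traces)                      # dF/F + smoothing
results = analyze_traces(dffs)                       # pooled oscillation call
summary = summarize_group(results, group="demo culture")
print(f"{summary.n_oscillating}/{summary.n_rois} ROIs oscillating "
      f"({summary.percent_oscillating:.1f}%)")
mean_hz, sd_hz = summary.normal_fit
print(f"oscillation frequency: {mean_hz:.2f} +/- {sd_hz:.2f} Hz (Normal fit)")
```

prints

```
14/40 ROIs oscillating (35.0%)
oscillation frequency: 2.11 +/- 0.61 Hz (Normal fit)
```

Of the 20 planted oscillators, 14 are called significant and every call
lies within one spectral bin (0.125 Hz) of its planted frequency; the
remaining units are transient-only or silent and none of them is falsely
called. The pooled top-75% rule is deliberately conservative — by
construction it discards a quarter of all detected peaks — so the
percentage of ROIs called oscillating understates the planted fraction.

A full multi-group run (simulate → extract → ΔF/F → spectra → cluster →
two-way ANOVA report) is available both as a library call
(`calcispect.run_pipeline`) and as a CLI:

```sh
calcispect simulate --config sim.yaml --out-dir data/ --seed 7
calcispect extract-rois --movie data/movie.tif --out-dir rois/
calcispect run --config run.yaml --seed 7 --out-dir results/
calcispect quantify-volume --gfap g.tif --tubulin t.tif
```

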