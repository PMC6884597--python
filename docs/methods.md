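# Methods

This note documents the models, conventions and design choices behind
`calcispect`, in the order the pipeline runs them.

## Synthetic cultures

The generator plants `n_rois` units, each assigned one of three activity
classes: *oscillatory* (a sinusoid at a frequency drawn uniformly from
`oscillation_freq_range_hz`, default 0.5–3 Hz, with random phase),
*transient-only* (Poisson-timed events at `transient_rate_hz`, default
0.2 Hz, convolved with a difference-of-exponentials calcium-indicator
impulse, rise 50 ms / decay 500 ms, normalized to unit peak), or *silent*.
`fraction_oscillatory` sets the oscillatory share; `fraction_transient`
(an addition to the configuration, default: half of the remainder) splits
the rest between transient-only and silent.

A unit's raw trace is `F(t) = B·(1 + s(t)) + B·drift(t) + B·a·η(t) +
B·σ·ε(t)` where `B` is `baseline_intensity` (default 100), `s` the clean
class signal scaled by `signal_amplitude` (default 0.5, i.e. a 50% ΔF/F
excursion — typical of bright synthetic indicators on strong events),
`drift` a slow sinusoid (`drift_amplitude` 0.02, period 120 s, standing in
for focus and bleaching drift), `η` unit-variance 1/f^χ noise obtained by
shaping white noise in the Fourier domain (`aperiodic_exponent` χ = 1,
`aperiodic_amplitude` 0.05 — a modest broadband background that gives the
detrending stage a realistic null), and `ε` white Gaussian noise
(`noise_sd` 0.05). All amplitudes are expressed relative to `B`, so the
signal-to-noise ratio of a trace is `signal_amplitude / noise_sd`
(default 10; the frequency-recovery validation uses 2). The recorded
`clean_trace` is `B·(1 + s)` — noise and drift excluded — so with all
three stochastic amplitudes at zero the returned trace equals it exactly.
No published amplitude or SNR exists for the recordings this emulates;
these defaults are assumptions, documented as such, not calibrated values.

Movies render each unit as an isotropic Gaussian spot (σ =
`roi_radius_px`/3, truncated at 3σ so spots of non-overlapping placement
discs never overlap) whose amplitude is modulated by the unit's signal,
plus per-pixel white Gaussian noise. The 1/f background is a trace-level
construct only; movie noise is spatially and temporally white. Placement
uses rejection sampling with a bounded retry budget and fails loudly when
the frame cannot hold the requested discs. One seeded `numpy` generator
drives everything; identical configurations are bit-identical.

What the generator does **not** emulate: optics (PSF, depth attenuation in
a 3-D scaffold), motion, indicator nonlinearity and saturation,
correlated network events across units, neuropil contamination. Passing
recovery tests on this data therefore demonstrates the correctness of the
algorithms under their stated assumptions, not robustness to every
real-recording artifact.

## ROI extraction

Per-pixel temporal variance (population convention, `ddof` configurable)
is smoothed with a 2-D Gaussian (`sigma_px` default 2.0; the value used on
real data should be derived from pixel size and magnification), reflective
boundaries. Seeds are local maxima at least `min_distance_px` (default 3)
apart with value ≥ `min_variance` (default: the 25th percentile of the
smoothed heatmap — permissive; for sparse fields of bright units a robust
threshold such as twice the heatmap median suppresses noise-born maxima,
and the parameter is exposed for exactly that reason). Regions grow from
each seed as the connected component above `rel_threshold` × seed value
(default 0.5, i.e. the half-maximum contour); contended pixels go to the
nearest seed, ties to the lower ROI id. The ROI trace is the single pixel
nearest the mask's center of mass — deliberately not a mask average,
matching the single-pixel convention of the upstream analysis this
reimplements.

## ΔF/F

`F₀(t)` is the mean of the samples *strictly below* the 80th percentile of
the window `[t − 15 s, t + 15 s]` (clipped at the boundaries; linear
percentile interpolation). The sliding window tracks slow drift while the
sub-percentile rule excludes sparse transients from the baseline. When the
strictly-below subset is empty — discrete or near-constant windows — the
implementation falls back to the non-strict subset (≤ percentile) and only
then to the window mean; the non-strict fallback keeps a two-valued trace
(baseline plus rare transient) anchored at its true baseline instead of
biasing it upward. Strictness and a whole-trace (`global_baseline`) variant
are exposed as options. `F₀ ≤ 0` anywhere is an error naming the ROI.
Smoothing is a Savitzky–Golay filter, order 2, window 11 frames (0.55 s at
20 Hz) — short enough to pass the 0.2–3 Hz band of interest essentially
untouched while suppressing frame-rate noise.

## Spectral analysis

Welch PSD: Hann taper, 8 s segments, 2 s overlap, per-segment constant
detrend, one-sided density scaling; frequency resolution 0.125 Hz. The
aperiodic component is removed by fitting a least-squares line to
log₁₀ PSD versus log₁₀ f over 0.2–8 Hz (capped at Nyquist) and
subtracting it — in log-log coordinates a 1/f^χ power law is exactly
linear, so a pure power law detrends to zero; a log-linear frequency axis
is available as an option. Zero PSD bins are floored at 10⁻³⁰⁰ before the
log so silent traces stay finite and detrend flat. Peaks are strict local
maxima of the detrended spectrum exceeding 3 × its SD over the fit band,
computed per ROI; a spectrum flat to 10⁻¹⁰ log-units is treated as
structureless (no peaks), which is a numerical floor, not a sensitivity
parameter. All peaks from one invocation are pooled and the top 75% by
height are retained ("top 75 percentile" read as retaining the top 75%,
cutoff at the 25th percentile of pooled heights; the inverted reading is
available via `keep_top_percent`). An ROI oscillates iff it retains at
least one peak, at the frequency of its tallest survivor. Band power is
the trapezoidal integral of the linear PSD over [0.2, 3] Hz with
interpolated band edges. Frequencies of oscillating ROIs are summarized by
a Gaussian maximum-likelihood fit (sample mean, population SD).

Because the pooled rule discards a quarter of all detected peaks by
construction, and because low-frequency oscillators compete with the 1/f
background, the fraction of ROIs called oscillating systematically
understates the planted fraction; the calls it does make are, on the
synthetic conditions above, essentially always at the correct frequency
(within one Welch bin).

## Cluster analysis

The 8 features per ROI: mean, SD and skewness of ΔF/F; transient count per
minute (upward crossings of median + 2 SD) and mean transient amplitude
(epoch maxima); band power [0.2, 3] Hz; dominant frequency (PSD argmax in
0.2–8 Hz); spectral Shannon entropy of the normalized PSD over 0.2–8 Hz.
This default set captures amplitude, event and spectral structure; it is
pluggable (`FeatureVector` accepts any 8-vector) for users with a
different canonical definition. Non-finite values (skewness of a constant
trace) fall back to 0.

Features are z-scored across ROIs (zero-variance features map to zero)
before Euclidean distances; the graph weight is `1/(d + ε)` with
ε = 10⁻⁹, so identical ROIs get a large finite weight. Louvain community
detection (networkx backend, resolution 1) is repeated `n_runs` = 100
times with sub-seeds from one master `SeedSequence`; the co-assignment
matrix (fraction of runs pairing i with j) is thresholded at τ = 0.5 and
re-clustered, iterating until all runs agree (at most 10 iterations, then
a warning flag). The partition reports both the modularity of the
consensus labels on the original graph (the headline quality index) and
the mean per-run modularity. Dunn's index uses the classical definition —
minimum single-linkage inter-cluster distance over maximum intra-cluster
diameter, diameters floored at ε so coincident clusters score 0 — computed
on a 2-D UMAP embedding (15 neighbors, `min_dist` 0.1, seeded; cohorts no
larger than the neighbor count fall back to PCA with a warning, since the
UMAP neighbor graph is undefined there).

## Volume quantification

Stacks are binarized as whole volumes (not per plane, not max-projected):
Otsu's threshold on the pooled voxel histogram by default, a fixed
threshold as override; "positive" means above-threshold signal regardless
of display polarity. An all-equal stack binarizes to all-background with a
warning. Volume fraction is foreground voxels over total voxels across
all planes; the astrocyte-to-neuron ratio divides the GFAP fraction by the
β-III tubulin fraction and is undefined (an error) when the neuron channel
is empty.

## Orchestration and statistics

`run_pipeline` derives every stage seed from one master seed, pools the
oscillation call across all ROIs of the invocation, clusters per group,
and writes per-ROI and per-group tables plus a manifest keyed by a hash of
the configuration (excluding the output path, so the hash identifies the
analysis). Group comparison is deliberately thin, off-the-shelf
statistics: two-way ANOVA (time point × construct, type II) with Tukey HSD
at α = 0.01 on per-ROI band power, and a one-way Tukey–Kramer variant for
per-cluster contrasts; both reject designs with missing cells or
single-observation cells.

## Validation problem sizes

The acceptance computations use 200 ROIs (frequency recovery at SNR 2),
two 100-ROI cohorts (detection separation), and 120 ROIs with 100 Louvain
runs (cluster recovery) — cohort sizes chosen to match the scale of the
per-construct ROI counts the method is designed for while keeping a full
validation run around a minute on one core.

## Known limitations

- The oscillation-call rate depends materially on two conventions the
  method leaves open (pooled-percentile direction, per-ROI vs pooled SD in
  the 3×SD rule); both are exposed as parameters, and absolute percentages
  should be compared only within one convention.
- Single-pixel traces are noisier than mask averages; the choice is
  fidelity to the upstream convention, not noise-optimality.
- The consensus procedure guarantees stability, not global modularity
  optimality; near-degenerate graphs can converge to different partitions
  under different master seeds (the planted-structure tests bound this in
  practice).
- Dunn's index is computed on the 2-D embedding, so its absolute value
  inherits UMAP's distortions; only comparisons under the same embedding
  parameters are meaningful.
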