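# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the package, stage by stage.

## Indicator forward model

Latent calcium `c` is expressed in single-AP equivalents.  Between
spikes it decays exponentially with time constant τ = 175 ms (the
published jRGECO1a decay time, interpreted here as the time constant of
the *latent calcium*, which is the convention of model-based AP
extraction; a fluorescence half-decay reinterpretation would only
rescale τ).  Each AP increments `c` by 1.  Fluorescence is

    ΔF/F(c) = A·c^n                      for c < 1
    ΔF/F(c) = A·c^n / (1 + γ(c^n − 1))   for c ≥ 1

with A = 0.15, Hill coefficient n = 1.9, saturation γ = 0.001.  The
piecewise form anchors the curve so one isolated AP yields exactly
A = 15% ΔF/F, keeps it continuous and strictly increasing, and makes
saturation negligible below roughly ten simultaneous APs (γ is small by
design; it only tames the c^1.9 growth at large bursts).  Slow signal
drift — including photobleaching-like trends — is modeled as a
multiplicative baseline b(t) bounded within ±3% (the drift parameter)
around 1.

## Spike inference (MAP decoding)

The decoder discretizes the latent state:

* calcium grid: c ∈ [0, 10] in 201 steps (0.05 AP-equivalents per step);
* baseline grid: 11 values spanning 1 ± 0.03, piecewise constant on
  10-s blocks, with block-to-block steps bounded by the drift bound;
* up to 6 simultaneous APs per frame (a 5-AP burst at 10-ms spacing fits
  inside a single 15-Hz frame, so multi-AP frames are common).

Each frame pays the Gaussian negative log-likelihood
(y − b·(1+ΔF/F(c)))²/(2σ²); each spike pays log(1/(ν·Δt)) with an
expected-rate prior ν = 0.3 Hz.  The jointly optimal path over all
frames is found exactly (on the lattice) by Viterbi dynamic programming;
the transition structure (deterministic decay plus 0–6 spikes, snapped
to the nearest grid point) keeps the per-frame cost linear in the number
of lattice states, and the inner loop is JIT-compiled (numba), decoding
a 3,000-frame trace in ~0.1 s.  If the optimal path touches the top of
the calcium grid, the result is flagged (`clamped`) and a warning is
raised — counts in frames beyond ~10 simultaneous APs saturate rather
than error.

The noise σ is estimated as `MAD(first differences)/(0.6745·√2)`, a
robust high-frequency estimator that ignores the sparse, temporally
correlated calcium transients.  For CA1 recordings the estimate is
inflated by 1.5× (per-cell) to lower the false-positive rate; DG uses
1.0×.  A floor of 2×10⁻³ ΔF/F keeps the residual term well conditioned
on noise-free synthetic input, where the raw estimate approaches zero.
Grid snapping leaves sub-grid residuals (≲0.015 ΔF/F near c = 1), but
these cannot be absorbed by integer spikes (0.15 quanta) and therefore
do not perturb counts; noiseless traces with isolated 1–3-AP events are
decoded exactly, and at σ = 0.02 (the typical in-vivo noise level after
frame averaging) event F1 stays above 0.99 with spike-count error below
1% on 0.2-Hz trains.

## Preprocessing

Consecutive frame pairs are averaged (30 → 15 Hz), improving SNR by √2;
a trailing odd frame is dropped, and averaging preserves the mean of the
retained frames exactly.  Rigid drift is corrected by integer-pixel
translation registration: the shift maximizing the circular
cross-correlation of mean-subtracted images within a ±`max_shift` window
(FFT-based), against a reference image (mean of the first 50 frames by
default, configurable to a single frame).  Shifted-back frames are
filled at the exposed edges with the frame median, not zero, to avoid
biasing ROI means near borders.  Averaging precedes registration (a flag
swaps the order); subpixel and non-rigid motion are out of scope — the
synthetic motion model is integer rigid shifts, and annulus-mean
extraction is robust to sub-pixel residuals.

## ROIs and contrast QC

Somata of cytosolic-indicator-expressing neurons are bright rings around
a dark nucleus.  An ROI is the set of pixels at distance
[r_in, r_out] from the cell center (defaults 3 and 6 px at the synthetic
scale; real radii depend on magnification and are configurable), minus
the axis-aligned 5×5 nuclear patch centered on the integer-rounded
center.  ROIs losing more than 25% of their nominal annulus to the frame
boundary are rejected.  The trace is the unweighted pixel mean per
frame — extraction is exactly linear in the movie.

Contrast = (mean ring − mean nucleus)/mean nucleus, computed on the
temporal-mean image (chosen over per-frame contrast for noise
robustness).  It is gain-invariant but offset-sensitive, which is the
point: it degrades as chronic-window image quality decays.  Cells below
the QC threshold (default 0.2 — "very low contrast" is inherently a
judgment call, so the threshold is recorded per run) are excluded, and
sessions with no surviving cells are flagged.

## Synthetic data generator

The generator defines the study conditions for every test:

* **Spike trains**: a superposition of a Poisson process of burst events
  (each emitting a geometric number of spikes at 10-ms spacing — the
  intra-burst interval is a free design choice, as typical CA1 complex
  spikes fire at 100–250 Hz) and an independent Poisson process of
  isolated spikes.  Trailing bursts are truncated at the recording end.
* **CA1 preset**: isolated rate 0.18 Hz, burst-event rate 0.006 Hz,
  mean 5 spikes/burst, plus a lognormal per-cell rate scale (σ = 0.8,
  median 1).  The lognormal spread reflects the well-documented
  lognormal distribution of hippocampal firing rates, and it is also
  what makes *population medians* track multiplicative rate changes: for
  a homogeneous population the session median is dominated by Poisson
  counting skew and does not scale with the rate multiplier.  Calibrated
  by Monte Carlo, the preset gives a median per-cell average rate of
  ~0.21 Hz over 200 s.
* **DG preset**: 65% of cells silent (zero-rate mixture component), the
  remainder sparse (isolated 0.02 Hz, bursts 0.004 Hz, same lognormal
  spread), giving roughly one third of cells with ≥1 AP per session.
* **Timeline**: per-day rate multipliers applied to both rate
  parameters.  The demyelination/remyelination preset drops to 0.43 at
  day 9, declines to 0.165 by day 53, rebounds to 0.70 at day 58, and
  settles at 0.435 by day 100; optional mid-diet rebound bumps are off
  by default.  The control preset is identically 1.
* **Movies**: each cell is rendered as an annulus whose temporal signal
  is `gain·(1 + ΔF/F)` from the forward model, with the nuclear disc at
  the cytosolic resting level divided by (1 + contrast) — so the
  measured contrast equals the programmed value by construction
  (CA1 range 2–4, DG 0.6–1.2).  Integer per-frame shifts are applied
  before noise; noise is additive Gaussian by default with a Poisson
  shot-noise mode behind a flag.  Overlapping somata warn rather than
  error.  Movies are written as 16-bit unsigned multi-page TIFF.
* **Traces mode** skips rendering: raw F = F₀·b(t)·(1 + ΔF/F) + noise
  with F₀ = 1000, a random linear drift within the ±3% bound, and
  Gaussian noise of 0.02 ΔF/F by default (matching the inference
  benchmark conditions).

What the generator does **not** emulate: neuropil contamination,
overlapping-source crosstalk, z-drift, nonstationary noise, slow
photobleaching beyond the bounded drift term, or subpixel/non-rigid
motion.  Tests passing on this synthetic data therefore validate the
algorithmic chain, not robustness to those real-data artifacts.

## Activity metrics

Average rate = total APs / recording duration.  Maximal instantaneous
rate = peak count over non-overlapping 1-s bins aligned to the recording
start.  A burst is ≥5 APs within a 660-ms window; windows are anchored
at spike times, and the burst count is the largest set of pairwise
disjoint qualifying windows (greedy interval scheduling).  This
collapses overlapping windows into single events while guaranteeing the
count can only grow when spikes are added — a pure transitive merge of
overlapping windows violates that monotonicity when new qualifying
windows bridge two previously separate bursts.  Session summaries
(fractions active/bursting, median and quartile rates) are taken over
*all* segmented cells including silent ones, so medians can legitimately
reach zero late in the diet period.

## Statistics battery

All tests are two-sided with α = 0.05.

* **Wilcoxon rank-sum** (per-cell rates between two dates, within
  mouse): midranks for ties; exact null enumeration (dynamic-programming
  count of the Mann–Whitney U distribution) when min(n, m) ≤ 8 and no
  ties; otherwise a normal approximation with tie-corrected variance and
  continuity correction.  A fully tied comparison reports p = 1.
* **Mann–Kendall** (per-mouse median-rate trend over the diet-period
  dates): S = Σ_{i<j} sign(x_j − x_i), tie-corrected variance, ±1
  continuity correction; tau = S/(n(n−1)/2).
* **Paired t** (per-group median-rate change between two dates); a zero
  difference variance raises a degenerate-sample error rather than
  reporting an infinite statistic.
* **Repeated-measures group × time model**: the reported three p-values
  (time, group, interaction) come from a balanced two-way split-plot
  ANOVA in closed form (mouse as the repeated unit; group between,
  day within; mice with missing days are excluded listwise with a
  warning).  The implementation matches pingouin's mixed ANOVA exactly
  on balanced tables and is additionally validated against a
  subject-level permutation test of the interaction.  A full REML mixed
  model was deliberately not used: with complete per-mouse day sets the
  split-plot decomposition is exact and transparent.
* **One-way ANOVA + Bonferroni** (EPSP peak and area across diet
  durations): standard F, pairwise two-sample t-tests with p multiplied
  by the number of comparisons and clipped at 1.

## Evoked EPSP quantification

Synthetic sweeps: zero baseline, a one-sample square stimulus artifact
at onset, a biphasic afferent-volley wavelet (Gaussian derivative,
center 1.5 ms, width 0.3 ms) scaled to a requested peak-to-trough
amplitude, and an alpha-function EPSP a·(t/τ)·e^{1−t/τ} beginning 3 ms
post-onset whose analytic peak equals the requested amplitude (≈2 mV in
the control preset, τ = 10 ms).  Measurement windows default to
artifact 0–0.5 ms, AV 0.5–3 ms, EPSP 3–50 ms post-onset (acquisition
software cursors replaced by fixed windows).  Baseline is the
pre-stimulus mean (≥5 ms required); peak is max |V − baseline| in the
EPSP window; area is the trapezoidal integral rectified to the response
polarity, reported in mV·ms (the natural unit for a ~2 mV, tens-of-ms
field response); AV is peak-to-trough.  The artifact window contributes
to no measurement, so an arbitrarily large artifact changes nothing.
Response polarity is configurable (field EPSPs are negative-going at the
electrode; magnitudes are reported).

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at desk scale:
trace-mode cohorts of 3 mice × 2–3 sessions × 50–100 cells at the full
200 s / 15 Hz per-cell conditions; movie-mode scenes at 128×128 px and
tens of seconds.  Monte-Carlo checks use 1,000–10,000 replicates for
scalar statistics and 20 seeds for the inference benchmark.  The
end-to-end recovery check compares the mean over 5 seeds of the
day-53/day-0 pooled median-rate ratio against the programmed 0.165; at
240 cells per day the per-seed sampling noise of the day-53 median (a
few APs per cell) is a relative SD of roughly 10%, which the 5-seed mean
reduces to ~4%.

Tie-breaks and degenerate inputs: constant traces give σ = 0 (floored in
the decoder); an empty spike train is "inactive" with zero rates; ratio
denominators in recovery reports guard against zero ground-truth counts;
identical-response ANOVA tables report F = 0, p = 1.

## Known limitations

* The decoder is exact only on its lattice; sub-frame spike timing and
  posterior uncertainty over trains are out of scope.
* Registration is integer-shift rigid only.
* The noise estimator is a declared stand-in for proprietary
  model-internal estimators; it is consistent for white Gaussian noise
  but will underestimate strongly correlated noise.
* The repeated-measures model requires balanced complete designs;
  unbalanced cohorts fall back to listwise exclusion.
* Median-ratio recovery depends on the generator's rate heterogeneity
  assumption (lognormal); homogeneous-rate populations would need
  mean-based rather than median-based trajectories.
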