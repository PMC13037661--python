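# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `megdigits`.

## Pipeline overview

Sensor epochs (trials × channels × samples, aligned so that 0 s is the
EMG-defined movement onset, half-open time grid `[tmin, tmax)`) are
band-pass filtered, projected into a sensorimotor region-of-interest
(ROI) source space with an LCMV beamformer, summarized as
activation-index maps, and decoded with linear one-versus-rest
classifiers under stratified 5-fold cross-validation.  Group-level
inference uses nonparametric permutation machinery throughout.

## EMG timing

Raw EMG is band-passed 20–450 Hz, full-wave rectified and smoothed with
a 50 Hz low-pass; all filters are 4th-order Butterworth applied
forward–backward (zero phase), so the envelope carries no group delay —
a precondition for using threshold crossings as onset estimates.  The
per-trial threshold is `T = μ + kσ` with `k = 2` and μ, σ the mean and
(n−1) standard deviation of the trial's envelope; the first sample
strictly above T is the onset, the last sample of the final
above-threshold run is the offset (a `last_drop` variant returns the
sample after it; both are exposed because the verbal rule "the last time
point at which the signal dropped below the threshold" is ambiguous by
one sample).  Whether the epoch statistics should include the burst or
only a pre-cue baseline is equally underdetermined; the full epoch is
the default, a `baseline_window` option restricts it.  Reaction time is
cue-to-onset; movement time is onset-to-offset.

## Forward model and simulation

The forward model is the closed-form field of a current dipole in a
homogeneous conducting sphere (Sarvas form), sampled by radial
magnetometers on an outer cap.  Radial dipoles are magnetically silent
in this model, so source orientations are constrained to the local
tangential plane.  Geometry defaults: cortical shell radius 7 cm,
sensor shell radius 10.5 cm (≈ 3.5 cm scalp-to-sensor standoff, typical
of a SQUID helmet), ROI cap half-angle 0.5 rad (a patch ≈ 3.5 cm in
radius, the scale of the pre- plus postcentral hand region), 200
vertices and 64 channels at desk scale (both configurable down to the
minimum of 2 vertices / 8 channels).  Orientations are spatially
coherent — the tangential projection of a common random direction plus
30% per-vertex jitter — because the pyramidal-cell dipoles of a small
cortical patch are locally aligned; independent random orientations
would let a cluster's dipoles cancel, which is anatomically wrong and
destroys localizability for entire clusters.  A smooth random-gain
forward (`forward="random"`) exists for tests that need no physics.

The signal generator emulates, per trial of task *k*:

* **Phase-locked low-frequency bumps** (δ at 2.5 Hz, σ = 0.40 s; θ at
  6 Hz, σ = 0.20 s): Gaussian-windowed cosines of fixed polarity
  peaking at 0 s with ≤ 50 ms uniform latency jitter and 20% amplitude
  jitter, placed on task *k*'s vertex cluster (default 5 vertices,
  cluster centres ≈ 12 mm apart — per-finger cortical separation is not
  an empirically fixed quantity, so it is exposed as
  `cluster_separation`).
* **Sensorimotor rhythms** (α 10 Hz, β 20 Hz) with random phase per
  trial on a task-shared central vertex set; their envelope dips by 60%
  around execution (ERD) and rebounds by 50–60% about 0.7 s after
  movement offset (ERS).
* **High-γ bursts** (75 Hz, σ = 50 ms, random phase) at onset.
* **1/f background** at every vertex with amplitude 0.12 relative to
  the δ bump: weak enough that movement-locked δ activity dominates at
  active vertices — the regime in which activation maps are clean — yet
  strong enough that every vertex is always alive.
* **Sensor noise**: spatially white, scaled so that projected-signal to
  noise power equals `snr` (default 1; `inf` disables noise).

Defaults follow the emulated experiment: 100 trials per task, epochs
−2 s to 2 s at 300 Hz.

The EMG generator produces baseline Gaussian noise (σ = 1) plus an
envelope-modulated noise burst per trial.  Reaction times are
N(0.643 s, 0.090 s) truncated to [0.30, 0.95] s; per-task burst
durations are N(μ_k, 0.09 s) with μ_k ∈ {241, 253, 289, 295} ms (the
across-task duration profile of the emulated study; the 0.09 s spread
is a within-subject trial-scatter choice).  The burst envelope has a
4-ms half-cosine attack with a 60% initial overshoot decaying over
30 ms — the sharp agonist burst of a ballistic extension — so that the
`μ + 2σ` threshold crossing is an unbiased estimator of the true onset;
a 40-ms decay closes the burst.  Per-task amplitudes (12, 16, 21, 27 ×
baseline, 15% lognormal-like jitter) and task-specific temporal
recruitment profiles (±40% sine modulations that vanish at the burst
edges) make the four classes linearly decodable.  The shape component
matters specifically: envelopes that differ only by a scale factor lie
on a single ray in feature space, and a one-versus-rest *linear*
classifier cannot isolate the middle classes of an amplitude-ordered
set; temporal profile differences restore linear separability, which is
also how real inter-finger EMG differs.

What the generator does **not** emulate: realistic head anatomy or BEM
forward fields, spatially correlated sensor noise, ocular/cardiac
artifacts, head movement, co-contraction or enslaving of neighbouring
fingers, and any nonstationarity across the session.  Tests passing on
this generator therefore demonstrate the correctness and calibration of
the pipeline's machinery, not expected performance levels on human
recordings.

## Beamformer

The data covariance is pooled over all trials and samples (channel
means removed, (n−1) normalizer, symmetrized).  Filters are
Tikhonov-regularized: `C → C + reg·mean(diag C)·I` with `reg = 0.05` by
default, the conventional loading for rank-deficient or noisy
covariances; `reg = 0` on a singular covariance raises with advice
rather than producing garbage.  For each vertex the free-orientation
(3-column) leadfield is reduced to its numerically non-silent column
space (the sphere model contributes at most rank 2), the vector
beamformer `W₃ = (LᵀC⁻¹L)⁻¹LᵀC⁻¹` is formed, and the reconstructed
3 × 3 covariance `W₃CW₃ᵀ` eigendecomposed; the dominant eigenvector is
the orientation of maximal variance.  The scalar filter along that
orientation is rescaled to exact unit gain `w·l = 1` (orientation sign
fixed by making its largest component positive).  Filters are fitted
once on all trials by default, replicating the analysis profile in
which source reconstruction precedes the cross-validation split while
activation maps are computed per training fold; fitting weights per
fold is available by calling `fit_lcmv` on a trial subset.

## Activation index

`A(i) = (wCs(i)wᵀ − wCb(i)wᵀ) / (wCs(i)wᵀ + wCb(i)wᵀ)` per trial *i*
and vertex, then averaged across the trials of each task.  Both
quadratic forms are computed as the variance of the reconstructed
source time course within the window, which is algebraically identical
to the quadratic form in the (mean-removed, 1/n) window covariance but
avoids forming channel covariances per window.  Mean-removed windows
are the default (a raw second-moment option exists; the distinction is
not fixed by the method's verbal description); the biased 1/n
normalizer matters for 15-sample windows and keeps the quadratic forms
consistent.  A is in (−1, 1) whenever both forms are positive, is 0
when they are equal, flips sign when windows are swapped, and is NaN
(with a warning) when both vanish.  Windows: baseline −2.0 to −1.5 s,
task −1 to 2 s for the full-epoch map; 50-ms non-overlapping tiles over
[−1, 2) — exactly 60 windows of 15 samples at 300 Hz — for the windowed
maps.  Extrema (per-task argmax and argmin, 8 vertices per map) break
ties toward the lowest vertex index and exclude NaNs; duplicates across
tasks are retained so the stated feature dimensionality is preserved.

ROI PCA is computed on trial-concatenated, time-demeaned source data
(the concatenation convention is a package choice); the smallest
leading component set whose cumulative explained variance exceeds 70%
is retained.

## Decoding

One harness serves every pipeline: `StratifiedKFold(5, shuffle)` with a
fixed seed, per-fold standardization fitted on the training fold, and a
linear one-versus-rest SVM (`C = 1`, configurable; the method
description names the classifier but no constant).  Feature steps that
aggregate over trials — PCA loadings, A-map extrema — are recomputed
inside each training fold, which coincides with the stated "maps from
80% of trials" protocol and guarantees no test-fold leakage; a
perturbation audit in the test suite verifies it.  Accuracies are
reported per fold, with the aggregated confusion matrix and
class-conditional recalls.

Virtual channels: windows whose window-wise decoding accuracy is
significantly above the 25% chance level (cluster-based permutation
test at α = 0.05) each contribute their 8 extrema vertices.  Each
window's channels carry that window's own time segment, intersected
with the significantly decodable point-wise spans (the window's span is
used verbatim if the intersection is empty on the resampled grid); δ/θ
series are resampled to 30 Hz before segment extraction to limit
dimensionality.  Single-window classification uses one window's
features; window-combined classification concatenates all decodable
windows' features in temporal order, so the combined scheme strictly
extends the temporal coverage of any single window.  Both schemes share
identical folds.  When the package is run on a single dataset, the
per-subject axis required by the cluster test is supplied either by
fold-wise accuracy series or by multiple simulated subjects
(independent generator seeds); the acceptance script uses seeds.

The feature builders accept a ``decim`` factor that subsamples the
feature time grid: band-limited source series are heavily oversampled
at 300 Hz, and nearly duplicated feature columns slow the margin solver
without adding information.  The default is 1 (no subsampling); the
calibration studies use 5–10.

## Statistics

* **Friedman**: scipy's implementation for ≥ 3 conditions; the same
  midrank statistic computed directly for the 2-condition case scipy
  rejects.
* **Wilcoxon signed-rank**: zeros dropped, midranks; exact sign-flip
  distribution for small tie-free samples, normal approximation with
  continuity correction (and tie-corrected variance) otherwise; the
  signed Z of the approximation is always reported.
* **Benjamini–Hochberg**: statsmodels step-up, verified against a
  brute-force implementation in the tests.
* **Cluster permutation**: per-point one-sample (or paired-difference)
  t across subjects; cluster-forming threshold the p < 0.05 t critical
  value with subject degrees of freedom (two-tailed for two-sided
  tests) — the method names no threshold, this is the field default;
  cluster mass is the summed t; the null is the maximum cluster mass
  over sign-flip permutations (5000 by default, seeded); p-values carry
  the +1 correction and are bounded below by 1/(n_perm+1).  The
  accuracy-vs-chance statistic is a t on the deviation from 0.25 (a
  rank alternative can be substituted by passing precomputed
  statistics).  Contiguity is along the time/window axis, and
  lattice-adjacency on frequency × time maps.  The implementation is
  vectorized over permutations (needed for calibration studies) and is
  cross-checked against `mne.stats.permutation_cluster_1samp_test` in
  the tests.
* **Vertex-wise tests**: one-sided sign-flip permutation on the
  across-subject mean deviation from chance, BH-corrected across
  vertices within each window.

## Digit maps

Each vertex × 50-ms window is decoded from its single-vertex segment
(same 5-fold harness; the per-vertex CV scheme is not fixed by the
method's verbal description, so the common harness is reused).
Individual labels take the class of highest class-conditional recall;
ties — including the all-equal degenerate case — are left unassigned
rather than broken arbitrarily, so they cannot inject spurious votes.
Group maps assign, inside the significance mask, the label most
frequent among subjects; tied votes are unassigned and logged.  The
per-finger activation threshold is 25% of one quarter of the maximum
total assigned vertex count across windows.

## Problem sizes

The package's own studies run at desk scale: 60 ROI vertices × 32
channels × 100 trials for the decoding studies, 200 × 64 for
localization recovery, 40 × 32 with 20–30 mm cluster separation for
digit-map recovery (clearly disjoint clusters are the regime in which
per-cluster label recovery is well-posed; at millimetre separations the
maps overlap, as they do in real cortex).  The feature-scheme and
window-combination comparison runs at sensor SNR 0.3 rather than the
generator default of 1: at saturating SNR every scheme decodes at 100%
and ordering comparisons are vacuous.  All sizes are configuration
parameters, and every simulation, fold split and permutation is seeded.

## Known limitations

* The sphere forward model has no anatomy; localization statements are
  about the method, not about cortical geometry.
* The beamformer assumes uncorrelated sources; the simulator's
  task-shared rhythms are correlated across vertices and are handled
  only insofar as they are suppressed as interference.
* Window-wise covariances on 15 samples of band-limited (hence
  autocorrelated) data are high-variance estimates; trial averaging is
  what makes the maps usable.
* The evoked/induced split is exact only in the arithmetic sense
  (induced ≡ total − evoked); pointwise negative induced power is
  possible and flagged rather than clipped.
* Aligned-rank-transform ANOVA with post-hoc estimated marginal means
  is not implemented; the Friedman/Wilcoxon/BH path covers the
  repeated-measures comparisons the package makes.
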