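# Methods

## Problem

Longitudinal resting-state fMRI is increasingly proposed as a biomarker of
disease progression, for example in multiple sclerosis. Before a
connectivity measure can track change, its test–retest reliability over the
retest interval must be established. This package implements the analysis
chain for a two-session (baseline BL, follow-up FU), two-group (healthy
controls HC, patients MS) design: subject-level network maps by dual
regression against template networks, and two complementary reliability
statistics — the intraclass correlation ICC(3,1) of per-subject summary
connectivity, and the Dice ratio of overlapping suprathreshold maps (R12).

## Dual regression

Given a stack of K template network maps and one subject-session 4D series:

- **Stage 1 (spatial).** Each volume, demeaned over the in-brain mask, is
  regressed jointly on the K template maps (columns demeaned over the mask).
  The coefficients across time give one time course per network.
- **Stage 2 (temporal).** The stage-1 time courses are demeaned and scaled
  to unit sample variance, then each voxel's demeaned time series is
  regressed jointly on all K of them. The coefficients are the subject's
  beta maps; dividing by the coefficient standard error (residual variance ×
  design Gram inverse, residual df = T − K − 1, the −1 for the removed voxel
  mean) gives the Z maps.

Both stages are multiple regressions over all networks simultaneously;
fitting one network at a time would leak shared variance between
overlapping networks. Variance-normalizing the stage-2 regressors makes the
beta and Z magnitudes comparable across subjects and sessions; without it,
the per-session scale of the estimated time courses would cancel the
subject amplitude signal entirely on noiseless data. The Z statistic is the
OLS t-statistic used directly: at ~150 time points the t→normal deviate
conversion changes nothing material, and the sign threshold Z > 0 used for
masks is identical under any monotone conversion (`t_to_z` is provided for
completeness).

Degenerate-voxel rules: a voxel with a constant time series gets
beta = Z = 0, keeping masks well defined. A voxel fit exactly (residual sum
of squares below 1e-20 of its total sum of squares — rounding level in
float64) has an infinite t-statistic; its Z is set to ±1e6 with the sign of
the coefficient so Z maps stay finite and sign-thresholding behaves.
Without this rule, noiseless simulations would produce arbitrary huge Z
values driven purely by floating-point residuals.

## Masks and summaries

- **Entire-network (EN) mask:** template voxels strictly above a threshold
  (default 0, i.e. the template's positive support). The default threshold
  matches the subject-level Z > 0 convention.
- **Subject-overlap ROI:** voxels with Z > threshold (strict, default 0) at
  *both* sessions for that subject. An empty overlap contributes a missing
  value to the ROI ICC (dropped pairwise, with a logged warning) rather
  than a zero: absence of suprathreshold signal is not the same as low
  connectivity.
- The per-subject summary is the arithmetic **mean** over the mask, taken on
  the Z maps by default (`use_beta=True` switches to beta maps).

## ICC(3,1)

From the subject × session table of summary values, the two-way ANOVA with
random subject effects and fixed session effects gives the between-subject
mean square BMS, the between-session mean square JMS and the residual mean
square EMS; then

    ICC(3,1) = (BMS − EMS) / (BMS + (k − 1)·EMS),   k = number of sessions.

The residual SS is computed from the interaction residuals
y_ij − ȳ_i· − ȳ_·j + ȳ_·· directly rather than by subtracting sums of
squares, which keeps the statistic stable (to ~1e-12) under large additive
session effects. A fixed session shift is absorbed entirely by JMS and
leaves the ICC unchanged — the property that makes this consistency form
appropriate for longitudinal data. Negative raw estimates are clamped to 0
for reporting (both values are returned); a table with zero total variance
makes the formula 0/0 and is reported as ICC 0 with a warning. At least 3
complete subject rows are required.

## Dice overlap R12

R12 = 2·V_overlap / (V1 + V2) over the strictly suprathreshold voxel sets
of the two sessions; undefined (an error, distinct from 0) when neither
session has suprathreshold voxels. Threshold sweeps return a missing-result
marker, not zero, where counts vanish. Note that at Z > 0 roughly half of
pure-noise background voxels are suprathreshold in each session, so
whole-volume R12 has a chance floor near 0.5; this is why observed values
cluster in a 0.6–0.75 band at Z > 0 and drop sharply at Z > 1.5, where the
chance contribution collapses.

## Group statistics

Between-group comparisons of reliability scores use two-sided
pooled-variance t-tests with the Bonferroni-adjusted level 0.05/9 = 0.0056
applied as a fixed significance level (not p-value multiplication).
Demographic tables recomputed from published summaries use the pooled
(Student) form because the published p-values reproduce under pooling and
not under Welch, and the Pearson chi-square without Yates correction for
the same reason. Recomputing the age comparison from the rounded printed
summaries gives p = 0.246 against a printed .24 — consistent with the
original value having been computed on unrounded data.

## Synthetic data generator

No public data accompany the design, so the generator produces studies with
known truth under the minimal model for which dual regression is the
correct estimator:

    data(x, t) = Σ_j map_j(x)·c_j(t) + ε(x, t),   ε ~ N(0, σ_noise²),
    map_ijs = template_j · (1 + b_ij + w_ijs + shift·1[s = FU]),

with b_ij ~ N(0, σ_between²) drawn once per subject × network and
w_ijs ~ N(0, σ_within²) per session, and c_j(t) independent standard-normal
time courses per subject-session. Templates are nonnegative Gaussian bumps
at distinct lattice positions, scaled to a Z-like peak of 5 (typical of
thresholded IC maps); placing them on a lattice keeps pairwise spatial
correlation below 0.5 so the regression dictionary is well conditioned, and
a grid too small for the requested number of networks raises a
configuration error. Keeping templates nonnegative (rather than mean-zero
standardised) makes "positive support" and "suprathreshold at 0" coincide,
so entire-network masks are well defined.

Defaults mirror the emulated study: 150 volumes at TR = 3 s, two sessions,
group sizes (14 HC, 20 MS), nine networks. The default grid is 24³ — large
enough for nine separable networks while keeping a full study desk-scale;
the variance-component defaults (σ_between = 0.5, σ_within = 0.1,
σ_noise = 1.0, session shift 0) place the simulated ROI reliability in the
high band reported for stable cohorts. A per-group σ_within override
(`sigma_within_by_group`) encodes group differences as greater
within-subject variability, the mechanism reported for patient groups. The
session effect is a multiplicative amplitude shift on all networks
(default 0) so the fixed-session-effect term of the ANOVA is exercisable.
Everything is deterministic given the config seed (independent seeded
streams per subject-session), float64 in memory, float32 on disk.

What the generator does **not** emulate: hemodynamic response shape,
physiological noise and motion, scanner drift, spatially autocorrelated
noise, inter-subject anatomical variability, and spatial (as opposed to
amplitude) map changes between sessions. Consequences worth knowing:

- Whole-volume R12 at Z > 0 depends only on voxel signs, which amplitude
  perturbations rarely flip, so R12 at Z > 0 is nearly insensitive to
  σ_within under this model; its sensitivity appears at magnitude-dependent
  thresholds (tested at Z > 1.5).
- Passing tests demonstrate correctness of the estimators and statistics
  under the stated model, not performance on real scanner data with
  registration error and structured noise.

## Problem sizes used in the checked runs

Unit and property tests run on 8³–12³ grids with 2–3 networks and 20–60
volumes, where loop-based least-squares oracles are affordable. The
qualitative reliability band is checked on a 16³ grid, nine networks,
10 + 10 subjects, 150 volumes. Null calibration uses 200 replicates of a
12³-grid, 3-network, 6 + 6-subject study. The ICC consistency check uses
n = 200 subjects and 10 replicates. These sizes make the whole suite and
the acceptance run complete in a few minutes on one CPU.

## Known limitations

- ICA estimation, preprocessing (motion correction, filtering,
  registration) and voxel-wise permutation inference are out of scope; the
  pipeline consumes aligned, denoised volumes.
- ICC confidence intervals are not provided; only the point estimate with
  its ANOVA components.
- Whether published "0.00" entire-network entries are clamped negatives or
  true near-zero estimates cannot be distinguished; both the clamped and
  raw estimates are returned so neither interpretation is lost.
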