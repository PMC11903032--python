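# Methods

`fcvar` implements a complete analysis chain for asking whether two (or
three) groups of subjects differ in the *across-subject variability* of
seed-based functional connectivity (FC), voxel by voxel, and for
characterizing where and by how much. This note documents the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Seed connectivity model

Each subject contributes several runs of volumetric BOLD time series. A run
is reduced to a time × voxel matrix over an analysis mask (gray matter).
Denoising removes nuisance structure by a single least-squares projection
per run: the regressor matrix contains an intercept, the supplied confound
columns (motion parameters, drifts, tissue signals, task regressors), and
discrete-cosine columns for every frequency outside the retained pass band
(default 0.01–0.1 Hz at TR = 2 s). Regressing on an out-of-band cosine
basis *jointly* with the confounds is the "simultaneous band-pass"
strategy: it avoids the artifact of sequential pipelines in which
regressing unfiltered confounds after filtering reintroduces out-of-band
variance. Collinear regressor columns are dropped deterministically
(left-to-right greedy rank check), and the projection is idempotent by
construction.

The seed time course of a run is the mean of the z-scored seed-voxel
series. Runs are concatenated after per-run standardization (making maps
invariant to run-level affine rescaling), and each voxel's Pearson
correlation with the seed course is Fisher-transformed, z = atanh(r), with
|r| clamped at 1 − 1e-7 so degenerate voxels stay finite. Zero-variance
voxels yield z = 0 with a warning; a zero-variance seed is an error.

CONN-style weighted-GLM connectivity is deliberately simplified to plain
Pearson correlation on the run-standardized concatenated residuals; the
task predictors are already in the confound model, and condition weighting
is second order for continuous multi-run series.

## Variance mapping

The core statistic is the Brown–Forsythe test applied at every voxel: with
d_ij = |y_ij − median_j| (deviation from the group *median*), the statistic
is the one-way ANOVA F on the d values across groups, df (k−1, N−k).
Median centering keeps the type-I error near nominal for skewed data, which
matters because across-subject Fisher-z distributions need not be
symmetric. The mean-centered (classical Levene) variant is available via
`center="mean"`. Voxels where every deviation is zero are flagged
degenerate (F = 0, p = 1). Even-sized-group medians use the midpoint
convention; there is no tie-breaking randomness anywhere.

Nuisance covariates (age, task accuracy, reaction time, …) are removed
*before* the test by per-voxel least squares in which covariate slopes are
estimated **jointly with group intercepts** (cell-means coding). Age
differs between groups in the study design this emulates; pooling without
group intercepts would alias the group difference into the age slope.
Only the covariate component is subtracted, so group location structure
survives for the mean-comparison maps, and the same residualized values
feed both the variance test and the ratio map.

The variability-ratio map divides the across-subject spread of one group by
the other at each voxel that survives inference. "Spread" is the sample SD
by default (interpretable on the measurement scale; "variability over twice
as large" means SD ratio > 2); a variance-ratio option exists because the
scale convention is not universal. Ratios are reported only inside the
vetted significance mask; voxels with a zero denominator are flagged NaN.

## Cluster-extent inference

Family-wise error over the mask is controlled by the classic Monte-Carlo
("AlphaSim-style") cluster-size simulation:

1. **Smoothness estimation.** Per axis a, the FWHM of the effective
   Gaussian autocorrelation is estimated from residual maps as
   `FWHM_a = voxel_size_a * sqrt(−2 ln 2 / ln(1 − s²_Δa / (2 s²)))`,
   where s² is the map variance and s²_Δa the variance of first differences
   along a (in-mask neighbor pairs only), averaged over maps. This inverts
   the lag-one autocorrelation of Gaussian-smoothed white noise. Axes with
   a degenerate argument (outside (0,1)) are reported as 0 with a warning.
   The residual maps fed to the estimator are the per-group median-centered
   FC values — they carry the null spatial correlation without the group
   effect.
2. **Null simulation.** Each iteration fills the grid with white Gaussian
   noise, convolves it to the estimated smoothness, re-standardizes within
   the mask, thresholds at the two-tailed normal quantile of the
   voxel-forming p (default 0.05), and records the maximum cluster size.
   The cluster-size threshold is the smallest integer s such that the
   fraction of iterations whose maximum reaches s is ≤ the corrected alpha.
   1000 iterations is the default; the threshold is stable well before that
   at these mask sizes, and up to 100,000 iterations are supported.
3. **Labeling.** Connected components of {p < voxel_p} under face
   adjacency by default (6-neighborhood; 18/26 configurable). Cluster ids
   are deterministic: size descending, ties broken by peak coordinate.

The voxel-forming threshold (p < 0.05 two-tailed) is a configurable
assumption; only the corrected level (p < 0.05) is fixed by the analysis
convention this package follows.

Gaussian convolution of null fields uses **wrap (circular) boundary
conditions**, so the simulated field is strictly stationary: reflect-style
boundaries inflate edge variance relative to the interior, which biases
both the null cluster-size distribution and the permutation null below
whenever the mask touches the volume edge. The wrap-around correlation
between opposite faces is harmless for masks smaller than the grid.

## Spatial map correlation with a smoothness-matched permutation null

Two unthresholded maps (e.g. the variability-difference F map and the
group-difference F map) are correlated voxel-wise within the mask. Because
both maps are spatially smooth, naive voxel shuffling understates the null
spread of r; each permuted map is therefore re-convolved with a Gaussian
kernel at the data's estimated FWHM (and re-standardized) before
correlating. The unsmoothed variant is reported alongside as a control
that the added smoothing does not itself manufacture association. Only one
map is permuted — a single exchangeable side suffices for the null of no
spatial association. p is two-sided on |r| with the add-one rule,
p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n), so p is never 0 and its minimum
is 1/(1+n). Default 10,000 iterations; 100,000 supported.

## Group means and subject factors

Group comparison of (residualized) FC uses the one-way ANOVA F per voxel
plus pooled-variance post hoc t maps per group pair (sign convention
group1 − group2; Welch available via flag). For k = 2 the F = t² identity
holds at every voxel and is tested.

Correlations of FC with continuous subject factors (age of first
hearing-aid use, duration of use, hearing threshold in dB) are Pearson
correlations of covariate-residualized FC against the residualized factor,
with p from the t transform at df = n − 2 − q. Missing factor values are
dropped listwise per factor with n reported (the hearing-threshold subset
is the motivating case). ROI-level analysis averages FC over each cluster
ROI per subject; the ROI × factor family is corrected with
Benjamini–Hochberg, and both uncorrected p and q are reported.

## Synthetic cohorts

The time-series generator emulates the structure of the motivating study:
two or three groups (defaults 16 deaf / 33 hearing, optionally 16 native +
23 delayed deaf), 10 runs × 180 volumes at TR = 2 s on a 2 mm grid, a
central cubic seed, one cubic effect region, 6 mm smooth noise, linear
drift plus six motion-like regressors mixed into every voxel with recorded
confound tables, and age / accuracy / reaction-time covariates whose group
means mirror the study (hearing group younger, deaf group less accurate).
Defaults plant mean Fisher z = 0.5 in the effect region with across-subject
SD 0.4 (deaf) vs 0.2 (hearing), i.e. a planted variability ratio of 2.

Each effect voxel's series is w_s·g(t) + ε; seed voxels are g(t) + η, with
g unit-variance white noise. The coupling w_s is solved in closed form so
the ideal measured correlation equals tanh(z_s), z_s ~ N(μ_g, σ_g²). Two
exactness details: (i) smoothed noise is re-standardized so the per-voxel
SD stays at `noise_sd` (circulant smoothing keeps this exact at edges);
(ii) the seed-mean noise variance entering the solve is computed from the
actual smoothing kernel applied to the seed indicator, since smoothing
correlates seed-voxel noise and the i.i.d. value σ²/n_seed would
under-state it. Seed noise uses a field independent of the target noise so
the closed form has no covariance term. The latent signal is white rather
than AR — band-pass filtering makes the spectrum irrelevant to FC recovery,
and whiteness keeps the coupling solve closed-form.

A faster map-level generator (`simulate_fc_cohort`) draws per-subject
Fisher-z maps directly for studies of the variance-mapping and cluster
stages: smooth measurement noise (per-voxel SD ≈ the z sampling error at
the study's series length, default 0.05–0.15) plus, inside each effect
region, μ_g + σ_g·f_s(v) where f_s is a subject-specific unit-variance
smooth field. Every region voxel then has across-subject SD exactly
√(σ_g² + noise_sd²) while nearby voxels decorrelate over the smoothing
scale. This mirrors real FC maps, where a subject's deviation from the
group mean is spatially smooth but not constant over a region; a rank-one
region (one value per subject) would make whole-region detection collapse
to a single voxel-level test, capping detection power at the per-voxel
rejection rate regardless of region size.

What the synthetic data do **not** emulate: hemodynamic response shape,
physiological noise and spike artifacts, spatial normalization error,
non-Gaussian FC distributions, and realistic anatomical masks. Passing
tests therefore certify the statistical machinery (calibration, recovery,
error control) under the planted model, not robustness to every property of
real BOLD data.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run on reduced grids chosen as the smallest sizes
at which the spatial statistics behave like the full-size problem: 20³–24³
voxel masks for cluster-level properties (a 6 mm kernel on a 2 mm grid is
~3 voxels FWHM, so a 24³ mask holds several hundred resels), 50–200
simulated cohorts for rate estimates, 400–500 Monte-Carlo iterations per
threshold, and 100 subjects × 1760 volumes for Fisher-z recovery. These
are the package's own verification sizes; all defaults for real analyses
are larger (1000+ Monte-Carlo iterations, 10,000+ permutations).

## Known limitations

- Cluster inference assumes Gaussian-shaped spatial autocorrelation;
  heavy-tailed smoothness (as in some real data) would make the Monte-Carlo
  threshold anticonservative. Random-field or permutation maximal-statistic
  corrections are out of scope.
- The weighted-GLM connectivity estimator of CONN is approximated by plain
  correlation; condition-weighted variants are not implemented.
- Grids must match exactly; the package never resamples images.
- The control-region omnibus comparison reported alongside the motivating
  analysis (a chi-square over atlas regions) has no documented construction
  and is not implemented.
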