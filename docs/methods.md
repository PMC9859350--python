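# Methods

This note documents the models implemented in `gonogo_bpi`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Task and timing model

The simulated paradigm is a cued equiprobable Go/NoGo task. Each trial
is a 100-ms cue, a 1000-ms cue–target interval, and a 100-ms target, so
target onset is always cue onset + 1.1 s. Four trial types occur 100
times each by default (go, nogo, and two ignore conditions in which the
cue already announces that no response will be required), in seeded
random order, with inter-trial intervals drawn uniformly from
{2.8, 2.9, 3.0, 3.1, 3.2} s. One hundred null events (fixation periods
of {3.0, 3.5, 4.0, 4.5, 5.0} s) are interleaved to decorrelate the
regressors. Acquisition constants: TR = 2 s, 3-mm isotropic voxels on a
40×48×40 MNI-like grid with the origin at the grid centre. The study's
two instruction sessions are collapsed into one schedule by default
(instruction identity does not change the modelled contrasts); a
`sessions=2` option concatenates two independent schedules.

## Behavioural model

Response times are shifted gammas: RT = 150 ms + Gamma with mean
(target mean − 150) and the target SD. Only mean ± SD are constrained
by the group summaries, so the gamma's right skew is a modelling choice
that keeps RTs positive and realistic. Defaults (trial level):
HC 384 ± 60 ms, OCD 491.1 ± 117.5 ms; Go omission 2.97% / 3.21%; NoGo
false alarms 0.35% / 0.43%.

For cohorts, the same numbers are used as **between-subject** mean/SD:
each subject's mean RT is Normal(group mean, group SD), trial-level SD
within subject defaults to 100 ms (a realistic within-subject spread;
it contributes only ~10 ms of extra SD to a 100-trial subject mean, so
the subject-mean distribution still matches the group summaries).
Omission and false-alarm percentages per subject are Gamma draws with
the group's between-subject mean/SD — exact first two moments and
guaranteed positive, unlike a clipped normal. With 34 vs 14 subjects
this reproduces the reported slowing effect (d ≈ 1.33), and the test
suite verifies the two-sample t exceeds 2 in ≥ 95% of 200 replications.

## BOLD forward model and first-level GLM

The haemodynamic kernel is the canonical double gamma
g(t; 6, 1) − g(t; 16, 1)/6, 32-s support, normalized to peak 1 (the
continuous peak value is located once by bounded scalar minimization,
so sampling at any dt is decimation-consistent). Signal is stick
functions at **target** onsets convolved with this kernel at 20×
oversampling; cues are intentionally unmodelled (the analyses concern
target-locked responses) and null events contribute nothing. Noise is
stationary AR(1) (default ρ = 0.3) plus optional slow cosine drift and
linear leakage of six simulated head-motion traces (smoothed random
walks, step SD 0.2 mm/deg).

The GLM is ordinary least squares per in-mask voxel with task
regressors, optional six motion columns, a unit-norm DCT-II cosine
high-pass basis (cutoff 128 s — a common default) and a trailing
intercept. Residual variance uses n − rank degrees of freedom;
rank-deficient designs are rejected with the offending columns named
(identified by pivoted QR). No AR(1) prewhitening is applied: the group
analyses consume only contrast point estimates, for which OLS is
unbiased, and the simulator's autocorrelation is mild; a whitening step
could be wrapped around `fit_glm` without changing its interface.
Registered contrasts: `nogo_minus_go` (+1 nogo, −1 go) and
`go_plus_nogo` (+1 each); the ignore regressors never enter contrasts.

## Group scenes and ground truth

`simulate_group_contrast_maps` bypasses time-series simulation and
draws subject contrast maps directly: truth field (spheres of declared
effect size) + group offset (patient group only) + RT-slope field ×
standardized centered RT covariate (patient group; slope is in contrast
units per covariate SD) + white between-subject Gaussian noise, then
Gaussian smoothing (default FWHM 8 mm). Ground-truth labels are a pure
function of the scene geometry: sphere interiors are positive/negative,
a transition shell of width 1.5 × FWHM around each sphere is
*ambiguous* — beyond it the Gaussian kernel's tail (> 3.5 σ) carries
under 0.3% of the peak, so "deep null" voxels are uncontaminated —
and everything else is null. Overlapping effect spheres with
contradictory signs are rejected.

What the generator does **not** emulate: physiological noise, scanner
drift nonstationarity, susceptibility artifacts, inter-subject
anatomical variability or registration error, non-Gaussian
between-subject effect distributions, and spatially varying smoothness.
Passing recovery tests therefore demonstrate the correctness and
calibration of the inference machinery under the stated generative
model, not robustness to every property of real data.

## Bayesian inference

The two-level Gaussian model with a single global prior variance λ on
the contrast is deliberately minimal: it captures the meaning of the
global shrinkage prior (on average, no whole-brain effect) without
reproducing any toolbox-internal hierarchical machinery. λ is estimated
by EM on the marginal likelihood; the voxel sampling variance s²_v is
the **between-subject** spread of the contrast (first-level residual
variances are not propagated). Numerical choices:

* EM initialization is the method-of-moments estimate floored at
  0.1 × mean(s²_v/n): λ = 0 is an absorbing fixed point of the EM map,
  so iteration must start in the interior. Convergence: relative change
  in λ < 1e-9 or 1024 iterations (tight enough that the fixed point
  agrees with a direct grid-search maximization of the marginal
  likelihood to better than 1e-4 on 100-voxel instances); λ is floored
  at 1e-12.
* γ under the default `one_prior_sd` rule is the single global scalar
  √λ̂, recomputed for every fit. An `absolute` rule accepts a
  user-specified γ in contrast units.
* Posterior tail probabilities and their log odds are computed through
  the log-CDF (`log_ndtr`), so LPO values are finite and accurate even
  for posteriors far from the thresholds; the three hypothesis
  probabilities sum to 1 by construction.
* Directional decisions require posterior probability strictly above
  P_thr; the practical-null decision is tie-inclusive (≥ P_thr), so a
  voxel exactly at threshold is called null rather than low-confidence.
* Voxels with zero between-subject variance are excluded from the EM,
  flagged, and labelled low-confidence — never silently dropped.
* `lpo_null` is the log odds of P(ROPE) against P(not ROPE); the null
  map needs its own odds convention and this is the symmetric one.

## Permutation cluster-level FWE

The frequentist maps are corrected with a max-cluster-size permutation
test rather than random-field theory: it is distribution-free, exact up
to Monte-Carlo error, and needs no smoothness estimation. Conventions:
cluster-forming threshold at p = 0.005 applied one-sided in the
hypothesized direction (hypoactivation: patients < controls; RT
dependency: negative slope), connectivity 18 (faces + edges) by
default, corrected p = (1 + #{perm max ≥ observed}) / (n_perm + 1) — the
"+1" counts the identity permutation analytically and keeps p > 0.
Permutation schemes: sign flips (one-sample), group-label permutation
(two-sample), covariate permutation (regression); the requested number
of permutations is capped at the number of distinct permutations with a
warning. The calibration experiment (200 null one-sample datasets of 16
subjects on a 20³ grid, 500 permutations each, lightly smoothed noise)
yields an empirical FWER of 0.04–0.07 at nominal α = 0.05 across seeds.

## Cluster reporting

Connected components are labelled at the chosen connectivity; size is
voxel count × |det| of the affine's 3×3 block (so always a multiple of
27 mm³ on the 3-mm grid), centroids are unweighted means of member-voxel
mm coordinates, and up to 8 local maxima of |value| are reported per
cluster with a greedy 8-mm minimum separation (26-neighbourhood maxima,
largest first). Anatomical naming is a free-text column; no atlas is
bundled. The external meta-analysis mask consumed by the conjunction
report is an optional input; the analysis scripts and tests use a
synthetic stand-in generated from the scene geometry.

## Validation problem sizes

The standard recovery scene is 40×48×40 at 3 mm (≈ 31k brain voxels),
n = 34 subjects, effects ± 3 between-subject SD, FWHM 8 mm. The FWER
calibration uses 200 datasets × 500 permutations on a 20³ grid. GLM
round-trip checks use 20-trials-per-type schedules on 4³ grids at noise
SD 0.1 (observed amplitude bias ≪ 1%). These sizes give stable
Monte-Carlo estimates while keeping the full suite fast.

## Known limitations

* The Bayesian model shares one λ brain-wide; spatially varying priors
  and first-level variance propagation are out of scope.
* OLS without prewhitening slightly mis-states first-level standard
  errors under strong autocorrelation; only point estimates are used
  downstream, so group inferences are unaffected.
* Real-data preprocessing (realignment, normalization, segmentation) is
  out of scope; synthetic data are generated directly on the analysis
  grid and only Gaussian smoothing is modelled.
* The behavioural generator treats trials as exchangeable; no
  sequential effects, fatigue, or post-error slowing.
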