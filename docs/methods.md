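# Methods

## Design and forward model

The simulator emulates a two-session fast event-related word paradigm: each
session presents `n_words = 20` words `n_reps = 3` times (60 trials), each
for 2 s, within a run of 487 volumes at TR 1 s. One session carries the
anxiety condition, the other the neutral condition. Inter-trial gaps are the
2-s stimulus plus a uniform 2–6 s jitter (onset-to-onset 4–8 s), rescaled
proportionally if the drawn gaps would overrun the acquisition window; the
run starts with a 10-s lead-in. The jitter distribution and randomization
constraints are package choices — fast event-related designs vary on these
points and nothing in the analysis depends on them beyond identifiability of
the single-trial GLM.

Each trial contributes `amplitude_pattern x HRF-convolved boxcar` to the
BOLD signal. The HRF is the canonical double-gamma (SPM shape: peak 6 s,
undershoot 16 s, ratio 1/6), taken from nilearn's kernel and applied by one
vectorized FFT convolution of all trial boxcars sampled at TR/16. Every
trial regressor is normalized to unit peak so fitted betas are in the same
units as the injected pattern amplitudes. Slow drift is a random
low-order cosine series (3 terms, amplitude 1 by default) and measurement
noise is white Gaussian (`noise_sd = 0.5` by default, i.e. half the standard
deviation of the unit-variance trial patterns — a high-but-not-noiseless
SNR regime in which single-trial patterns remain recoverable from 2-s
events, which is the premise of trial-wise RSA).

### Injected consistency

The quantity the analysis chain must recover is the within-condition
pattern consistency c: trial pattern i in a region is

    pattern_i = sqrt(c) * shared + sqrt(1 - c) * eps_i

with `shared` and `eps_i` independent standard-normal voxel vectors, so the
expected pairwise Pearson correlation between any two trial patterns equals
c exactly. Outside configured regions c = 0. By default the patient (AN)
group receives c = 0.7 in the MPFC-like fixture region for the anxiety
condition only, controls receive 0 — the regime the package's power checks
probe. Per-subject consistency is jittered (sd 0.08, clipped to [0, 1])
around the group base by a Gaussian latent.

Two empirical properties of the *measured* searchlight value are worth
noting. First, it is attenuated relative to the injected c: boundary
spheres mix background voxels in, and beta noise dilutes trial
correlations. Second, even the background is slightly positive (~0.05–0.1):
temporally adjacent trials share estimation noise in any single-trial
scheme, which correlates their beta maps. Both effects are common to real
LSS/RSA analyses; they cancel in between-group and between-condition
contrasts, which is why the inferential tests are calibrated even though
raw map values are biased.

### Clinical covariate coupling

The simulated HAM-A score is linear in the standardized injected-consistency
scalar plus independent Gaussian noise, so that the cohort-wide correlation
between HAM-A and injected c equals `covariate_coupling` (default 0.9, the
regime in which the brain–behaviour correlation analyses are expected to
detect the coupled region). Age and PDS marginals mimic an adolescent
patient/control contrast (patients younger and less pubertally advanced);
HAM-A uses a single cohort-wide marginal (mean 11, sd 7, clipped at 0) so
the coupling is not confounded with a separately imposed group shift —
group differences in HAM-A emerge through the coupling itself. Post-scan
anxiety ratings (0–10) are noisy monotone transforms of HAM-A and produce
occasional zeros, exercising the zero-rating exclusion rule.

### Atlas fixture

Six probabilistic regions mirror the anxiety-circuit roles
(amygdala/ACC/insula/MPFC thresholded at 0.5; the small VTA/BNST at 0.001).
Each region's probability profile is `p(d) = clip(1 - d/(2r), 0, 1)` around
its center, chosen so thresholding at 0.5 recovers the analytic sphere of
radius r. Centers are placed proportionally on the grid and checked for
non-overlap after thresholding. These are synthetic stand-ins: real-data
use supplies atlas volumes through the same `build_roi` interface.

## Single-trial estimation (LSS)

"Least-squares sum": trial i's design contains its own HRF regressor, one
regressor equal to the sum of all other trials' regressors, discrete-cosine
drift columns with periods above 100 s, optional confound columns, and an
intercept. OLS is solved per voxel through normal equations with shared
cross-products (equivalent to per-trial `lstsq` for the well-conditioned
designs enforced by a condition-number check; duplicate onsets are rejected
as rank-deficient). A single-trial run drops the empty "others" column.

Numerical contract verified by the tests: with noiseless data and trials
whose responses do not overlap in time, LSS betas equal the injected
amplitudes to machine precision and coincide with the all-trials
simultaneous fit — *provided the GLM carries no drift columns*, since
cosine drift regressors absorb part of the unmodeled other-trial residual
and perturb the target coefficient at the ~0.1 level. The exactness oracles
therefore fit with `drift_cutoff_s=None` on drift-free simulations; with
drift enabled (the default) recovery is approximate by design.

No spatial smoothing is applied anywhere (consistency is a pattern
statistic; smoothing would inflate it), and no slice-timing, motion, or
prewhitening models are included: synthetic runs are generated on a common
grid, and a confound-column hook exists for real data.

## Searchlight

Sphere membership is Euclidean distance <= radius in voxel units (radius 2
=> 33 voxels), center included, lexicographically ordered. Spheres are
clipped to the analysis mask; centers whose clipped sphere has fewer than
`min_voxels = 10` voxels are invalid (NaN). Trial vectors with zero
variance inside a sphere have undefined correlations; pairs involving them
are dropped from the mean (and counted) rather than imputed as 0. The
difference map subtracts raw r voxelwise, while ROI averaging uses Fisher z
— an asymmetry preserved deliberately because the two summaries serve
different roles (voxelwise subtraction keeps the map in r units; averaging
correlations is better behaved on the z scale). The implementation is
vectorized over center chunks and verified voxel-for-voxel against a naive
triple-loop oracle.

## ROI analysis

Thresholding is inclusive (>=). ROI scores are means of atanh(r) over valid
in-mask voxels, with |r| clipped at 1 - 1e-7 before the transform (a
saturated correlation would otherwise map to infinity). The group ANCOVA is
an OLS of score on group + age + PDS; the group F is the squared
coefficient t with 1 numerator df (at the full cohort of 47 this gives
F(1, 43)). Missing covariates trigger listwise deletion with the dropped
ids logged. The leave-one-region-out loop rebuilds the merged mask without
each region in turn (full mask + 6 omissions = 7 analyses at the default
atlas); a region contributing no valid voxels reproduces the full-mask
result exactly.

## Permutation inference and TFCE

All three designs (two-sample with covariates, one-sample via sign
flipping, covariate correlation) use the Freedman–Lane scheme: nuisance
effects are estimated, their residuals are permuted (or sign-flipped) and
re-added to the nuisance fit, and the full-model statistic is recomputed.
Exhaustive enumeration replaces random sampling when the rearrangement
space is small enough (all 2^n sign patterns; all C(n, n1) relabellings for
the two-sample design *without* covariates — with covariates the
within-group arrangement of residuals matters, so full random permutations
are used). p-values use the (b+1)/(m+1) estimator, so the smallest
attainable FWE p is 1/(n_perm+1) and p-values are never zero. Two-sided
questions are answered by two one-sided runs on +/- maps, mirroring how
directional contrasts are usually reported.

TFCE integrates `extent^E * height^H` over thresholds h = dh, 2dh, ... up
to the map maximum, with E = 0.5, H = 2, dh = max/100 and 26-connectivity —
the convention of the standard permutation tool in the field, stated here
explicitly because published analyses rarely print it. Only positive values
are enhanced; callers negate the map for the opposite direction. The
implementation matches an independent per-threshold flood-fill oracle
exactly at equal dh, and an isolated unit-height voxel converges to the
analytic integral 1/3 as dh -> 0.

## Clinical statistics

Both Welch and pooled two-sample t statistics are available from summary
data because published demographic tables mix the two variants; every
result names its variant. The rank-sum statistic follows the R
`wilcox.test` convention (W = rank sum of the first sample minus
n1(n1+1)/2) with exact p-values for small untied samples. ROI scores are
square-root transformed before Pearson correlations (a variance-stabilizing
choice for skewed consistency scores); the strict policy rejects negative
scores and names the offending subjects, with a signed-root fallback, since
mean searchlight correlations are expected positive but small negative
values can occur. Fisher's comparison of two correlations defaults to a
one-sided upper tail, with a two-sided flag. The printed z for the
reference comparison (r = 0.38 at n = 25 vs r = 0.02 at n = 22) is 1.21
from the rounded correlations; only the p-value (0.11) is asserted in
tests.

## Problem sizes used by the test suite

The parameter-recovery check runs the full study design — 47 subjects
(25 + 22), 20^3 voxel grid, 487 volumes x 2 sessions x 60 trials, c = 0.7
vs 0 in one region — with 1000 permutations for the group-difference and
correlation inferences (about 3 minutes on one core). Familywise-error
calibration uses 200 replicate null cohorts of 16 subjects on an 8^3 grid
with 100 permutations each and a coarser TFCE step (max/25); TFCE-based FWE
control is valid for any E/H/dh, so calibration at one parameter set
carries the property. Oracle-equivalence checks run on 8^3 (searchlight)
and 16^3 (TFCE) fixtures. The demo pipeline (`rsalight run`) defaults to a
12^3 grid, 250 volumes, 20 trials/session and 11 subjects.

## Known limitations

- No k-space physics, motion, distortion, slice timing, or autocorrelation
  modeling; noise is white and drift is smooth, so real-data SNR and
  temporal structure are idealized. Passing tests demonstrate correctness
  of the estimators and calibration of the inference under these
  assumptions, not robustness to acquisition artifacts.
- Native-to-standard-space registration is out of scope: all volumes must
  share one grid.
- The background consistency bias from shared estimation noise (see above)
  means absolute map values should not be read as pure pattern
  consistency; only contrasts are calibrated.
- The simulator's word-level structure (word_id, repetition) is carried in
  the event tables but trial patterns are exchangeable within condition;
  word-specific representational structure is not modeled.
- Sphere membership is computed in voxel units and assumes isotropic
  voxels (the simulator's grids always are); the CLI warns when a beta
  stack's voxel sizes are anisotropic, but does not resample.
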