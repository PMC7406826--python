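# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The voxel-wise path model

At each voxel v the mediator is the subject's Fisher-z seed-to-voxel
connectivity `M_v`; acceptance X predicts M (path a), M predicts symptom
severity Y controlling X (path b), and the indirect effect is `a*b`. All
three regressions (M on X, Y on X+M, Y on X) carry the same covariate set
(age, sex, BDI-II, DES-II) and an intercept. Symmetric covariate placement
is deliberate: it makes `c = a*b + c'` an exact algebraic identity of
least squares, which the tests use as a free correctness check (to 1e-8).
X and Y enter unstandardized by default; every statistic used for
inference (t, bootstrap p, joint-significance p) is scale-invariant.

Everything is computed through Frisch–Waugh partialling: X, Y and the
whole mediator matrix are residualised on `[C, 1]` once, after which each
voxel's coefficients and standard errors are closed-form expressions in
five cross-products. This is what makes 10,000 bootstrap draws per voxel
and thousands of permutation passes tractable on one CPU.

## Bootstrap inference

`bootstrap_paths` resamples subjects with replacement B times (default
10,000) and refits all paths per draw, vectorised across draws via batched
normal equations. P-values are two-tailed bias-corrected (BC) percentile
p-values: with `z0` the normal quantile of the fraction of draws below the
point estimate and `z_alpha0` that of the fraction below zero, the
one-sided p is `Phi(z_alpha0 - 2 z0)`; plain percentile is available.
P-values are floored at 1/B so log transforms stay finite. Degenerate
resamples — draws whose covariate matrix is collinear (e.g. a single-sex
resample) or whose partialled X or M carries no variance — are redrawn and
counted; more than 10% of B aborts with diagnostics. At n = 33 with four
covariates the degenerate rate is negligible; below n ≈ 14 it grows
quickly, which bounds how small a cohort the model can serve.

Per-voxel RNG streams are spawned from `(rng_seed, flat voxel index)`, so
results are independent of voxel ordering and trivially parallelisable.

Calibration, checked by simulation in the acceptance suite: with a planted
null `a = 0` (b = 0.45) at n = 33, B = 1000, the BC test of `a*b` at
alpha = 0.05 rejects at ≈ 0.06 over 400 datasets (the percentile flavor
sits near 0.025, the conservative edge).

## Cluster-extent FWE correction

The reported analysis thresholds the voxel map at p < 0.001 (two-tailed,
strict inequality) and corrects at cluster level at FWE p < 0.05. The
correction engine is a subject-permutation maximum-cluster-size null:
X is permuted under the Freedman–Lane scheme (the covariate-fitted part of
X is kept, its residuals are permuted), the voxel statistic is recomputed
for every permutation, supra-threshold voxels are split by the sign of
`a*b` (so clusters are sign-homogeneous) and grouped under an
18-neighbourhood (6 and 26 selectable), and
`corrected_p = (1 + #{perm max size >= observed size}) / (1 + n_perm)`.

Three cluster-forming statistics are implemented; the same statistic is
always used for the observed and the permuted passes, preserving
exchangeability:

* `joint` (default): joint significance of the indirect effect — a voxel
  is supra-threshold when both the a-path and the b-path t tests pass the
  primary threshold (voxel p = max(p_a, p_b)). This is the standard
  small-sample test of `a*b`; it matches the design in which the three
  effects are tested jointly at every voxel, and it is valid (conservative)
  under the null because P(max(p_a, p_b) < alpha) <= alpha under either
  single null and ≈ alpha² under the full null.
* `sobel`: first-order delta-method z for `a*b`. Simple, but markedly
  conservative at n ≈ 33; per-voxel power at the 0.001 threshold is about
  half that of the joint rule at the study's effect sizes.
* `bootstrap`: the BC bootstrap p for `a*b` forms the observed clusters
  and every null pass refits with `B_null` bootstraps. Faithful to the
  voxel-wise report but orders of magnitude slower, and `B_null` must
  exceed `1/alpha_primary` (the p floor is 1/B): with the 0.001 primary
  threshold, `B_null = 2000` is the default and anything at or below 1000
  is rejected. This floor interaction is why an analytic statistic is the
  default engine.

Voxel-wise *reporting* is unchanged by this choice: the maps written by
the mediation stage carry BC bootstrap p-values for a, b, a*b and c'.

Under fully null synthetic cohorts the family-wise false-positive rate of
the default engine is well below the nominal 0.05 (conservative), which
the acceptance suite verifies over 400 replicates.

## Preprocessing chain

Order: discard the first 4 volumes → motion QC → one nuisance regression →
4 mm FWHM Gaussian smoothing → 0.01–0.1 Hz band-pass (a flag can swap the
last two; the default order matches the emulated protocol).

* **FD** is the backward-difference sum of absolute translation deltas
  plus 50 mm times the sum of absolute rotation deltas (rotations are
  stored in radians; the 1.5° exclusion bound is converted internally).
* **Exclusion**: any |translation| > 1.5 mm, any |rotation| > 1.5°, or
  mean FD > 0.5 mm.
* **Scrubbing** is implemented as per-volume spike indicator regressors
  (FD > 0.5 flags t−1, t, t+1, t+2, merged), not as volume deletion.
* **Friston-24**: the 6 parameters, their one-volume lags (zero at t=0),
  and both sets squared.
* **CompCor**: noise-mask voxel series are linearly detrended and
  variance-normalised; the components are the top-k temporal singular
  vectors (unit norm, first nonzero element positive), k = 5 from the
  pooled noise mask by default (per-tissue extraction is possible by
  calling `compcor` per mask). Fewer noise voxels than k yields
  min(k, rank) components with a warning.
* **Regression** uses the pseudoinverse, so rank-deficient designs degrade
  gracefully (with a warning); residuals are orthogonal to every design
  column.
* **Smoothing**: per-volume separable Gaussian, sigma_axis =
  FWHM/2.3548/voxel_size_axis, nearest-neighbour edges (constant images
  are preserved exactly).
* **Band-pass**: a hard rFFT mask keeping lo ≤ f ≤ hi and zeroing DC —
  chosen over Butterworth because pass/stop behaviour is then exactly
  testable; linearity holds to 1e-8.

## The synthetic cohort generator

The generator defines the study conditions: 33 subjects (configurable; the
analysis scripts simulate 35 with two high-motion subjects so QC removes
them), 200 volumes at TR 2 s, 3×3×4.5 mm voxels on a 20×20×10 grid. The
brain is the inscribed ellipsoid (~1700 voxels); seed, target and noise
regions are disjoint boxes inside it. Behavioral marginals use the
cohort's descriptive statistics (AAQ-II 39.89 ± 11.03, CAPS-5 25.27 ± 11.0,
BDI-II 25.15 ± 13.62, DES-II 17.08 ± 23.89, age 40.36 ± 11.10 truncated to
18–65, 42.4% female).

Structural model on the standardized scale, with `x` the standardized
acceptance score: the latent mediator is
`M_latent = z0 + a x + eps`, `eps ~ N(0, 1 - a^2)` (unit variance,
baseline z0 = 0.25); the outcome is
`y_std = b (M_latent - z0) + c' x + gamma' C_std + e`, with small
covariate effects gamma = (0.05, 0.05, 0.15, 0.10) and `e` scaled so
var(y) ≈ 1. The CAPS-5 column is `25.27 + 11.0 y_std`. Defaults
a = −0.65, b = +0.45 follow the reported direction (acceptance lowers
seed–target connectivity; connectivity raises symptom severity);
c' = −0.52 makes the implied total correlation c' + a·b = −0.81 match the
observed behavioral correlation.

Imaging model: every voxel carries white noise (sd 1); brain voxels add a
slow drift and a rank-3 band-limited structured confound at amplitude 0.3,
which noise-mask voxels carry at loadings N(1, 0.2) — giving CompCor a
recoverable target whose removal is measurable above the 1/T projection
noise floor. Seed voxels share a band-limited (0.01–0.08 Hz) latent signal
s(t) so it survives the band-pass stage; voxels in the target region
(dilated by one voxel so smoothing sees a homogeneous neighbourhood) add
`w_i s(t)`.

**Coupling calibration.** The mediator is defined on the post-cleanup
Fisher-z scale, so `w_i` must be solved against what the cleanup does to
signal and noise: band-pass keeps the in-band fraction f of white-noise
variance, smoothing multiplies independent-noise variance by kappa (the
sum of squared kernel weights), and — crucially — the nuisance regression
is not spectrally flat: motion expansions, spike indicators and the
confound components overlap the narrow signal band far more than white
noise does. The generator therefore reconstructs, per subject, the exact
projector the analysis will use (its own motion trace → Friston-24, FD,
spike columns; its own confound time courses, which CompCor recovers
almost perfectly; trend; intercept), computes the expected retained
variance fraction g_s of a random band-limited signal and the surviving
in-band noise fraction v_n, and solves

```
w_i = noise_sd * sqrt(kappa * v_n / g_s) * r_i / sqrt(1 - r_i^2),
r_i = tanh(M_latent_i)
```

so the across-subject regression of observed z on x has slope ≈ a. CompCor
components beyond the planted confound rank are treated as random
directions in the projector expectation. Without the g_s/v_n correction
the recovered slope is biased low by roughly 15% — the signal loses ~40%
of its variance to the regression while white noise loses ~16%.

**What the generator does not emulate:** hemodynamics, spatial
autocorrelation of the noise (background mediator maps are spatially
white, so null cluster sizes are smaller than in real smoothed data — the
FWE check calibrates the procedure, not real-data cluster extents),
scanner artifacts, anatomical variability, and laterality (one seed box
standing for a hippocampus; real-data mode takes per-hemisphere masks).
Passing tests therefore demonstrate correctness of the machinery under a
known generative model, not performance on real BOLD data.

## Power analysis

`mc_power_indirect` implements the CI-based Monte Carlo method: per
replication, draw n observations from the trivariate normal implied by the
input correlations (the "correlations for paths a and b and for path c'"
are read as corr(X,M), corr(M,Y), corr(X,Y) — the input convention of the
web tool this method is known from; a non-positive-definite triple is
rejected by name), fit `M ~ X` and `Y ~ X + M`, draw 20,000 independent
normal (a*, b*) pairs at the fitted estimates and standard errors, and
count the replication a success when the equal-tail 95% interval of
`a* b*` excludes zero. Defaults: 1000 replications, 20,000 draws, 95% CI.

Residual-variance convention: the reference tool fits by structural-
equation maximum likelihood, whose variance estimates divide by n rather
than the OLS residual df. `se_method="ml"` is therefore the default
("ols" selectable); at n = 33 the two conventions differ by about 0.03 in
power, and only the ML convention reproduces the published 0.75.

## Problem sizes used in the test suite

The acceptance-style checks run at desk scale, chosen as the package's own
test design: power at the published settings (1000 replications);
decomposition identity on 500-voxel problems; bootstrap type-I calibration
over 400 datasets at B = 1000; parameter recovery through the full image
pipeline at n = 500 subjects; cluster detection over 60 full-pipeline
replicates at n = 33 with 300 permutations (60 replicates give ~95% power
to distinguish a ~0.6 detection probability from the 0.5 boundary); null
FWE calibration over 400 mediator-level cohorts at 200 permutations.
Voxel-wise bootstrap maps in the analysis scripts use B = 2000 and 500
permutations; the library defaults remain 10,000 and 1000.

## Known limitations

* The manual, landmark-based hippocampal subdivision cannot be automated
  from a description; the geometric thirds rule (equal slice slabs along
  the anterior–posterior axis, extra slices anterior) is the documented
  synthetic/fallback proxy, and real-data mode consumes pre-labeled masks.
* The original cluster-level FWE engine is unknowable from the report;
  the permutation max-cluster-size null is implemented because it is
  assumption-light and exactly testable. Corrected p-values are valid but
  conservative under the simulated null.
* No slice-timing correction, realignment, segmentation or spatial
  normalization: these standard registration steps are consumed as
  precomputed inputs (motion files and masks).
* No moderated/multilevel mediation, latent-variable SEM, robust standard
  errors, Gaussian-random-field or TFCE correction.
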