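# Methods

## The validation model

The marker under study is a frozen linear rule for treatment response in
social anxiety disorder, ΔLSAS = β_b·baseline_LSAS + β_c·amyg_conn + β_0 with
β_b = 0.6194, β_c = 8.6290, β_0 = −9.9763. ΔLSAS is defined as baseline −
post (positive = improvement), so β_b > 0 encodes "more severe patients
improve more" — partly regression to the mean, partly true dependence. The
package applies the rule two ways:

- **uncentered** (`ORIGINAL_MODEL`): the published equation verbatim;
- **centered** (default for validation): baseline and the observed outcome are
  mean-centered within the analyzed cohort and the intercept is dropped.
  `amyg_conn` is already mean-zero by construction (cohort z-scoring), so the
  centered predictions equal the uncentered ones minus their cohort mean — an
  identity the test suite checks to 1e−10. Centering the observed outcome as
  well keeps residuals comparable between the two variants.

The compact benchmark is the same rule with β_c·amyg_conn removed. The frozen
baseline slope is used in the compact model by default (a cohort-OLS variant
is available through `compare_beta_sources`, which reports the prediction R²
of the OLS slope relative to the frozen one — near zero when the slope
transfers).

## Metrics and inference

`prediction_r2` = 1 − MSE(full)/MSE(compact) is an absolute
error-reduction measure; it is ≤ 1, unbounded below, and invariant to joint
relabeling of subjects. `model_based_r2` squares the observed-vs-predicted
Pearson correlations and reports full-minus-compact. Both are recomputed
from their definitions by independent oracles in the tests (agreement to
1e−12 on 1000 random instances).

The permutation test shuffles **only** the connectivity term; the
baseline–outcome pairing is never broken, so the null preserves the compact
model's fit exactly. For every shuffle the full-model predictions are rebuilt
with the frozen coefficients. Reported are the add-one p-value
(1 + #{null ≥ observed})/(1 + B) and the null's 95th percentile (`crit95`);
rejection by `observed > crit95` with B = 999 has true level ≈ 0.055 by the
usual discreteness of percentile thresholds, which is what the calibration
checks measure. Permutations on which a metric is undefined (degenerate
variance) are redrawn and counted; with continuous data this never triggers.
Permuting the already z-scored term is equivalent to re-z-scoring after the
shuffle, since standardization is permutation-invariant.

Exhaustive enumeration of all n! orderings at n = 6 serves as the oracle for
the sampled p-value (agreement within 3 Monte-Carlo standard errors).

## Power and confidence intervals

`correlation_power` is the two-tailed Fisher-z power: with
λ = arctanh(ρ)·√(n−3), power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2}); at ρ = 0
it returns α exactly. At ρ = 0.3, n = 40 it evaluates to 0.4693 — the "under
50% power for a medium effect" regime at this design size.
`r2_confidence_interval` back-transforms arctanh(r) ± z_{(1+level)/2}/√(n−3)
by tanh and squares the endpoints (percent scale); an r-interval straddling
zero clamps the lower variance bound to 0. At r = 0.46 (√0.21 rounded to two
decimals), N = 38, the 95% interval is 2.7%–46.2% variance explained; the
two-decimal rounding of r is the convention under which these round endpoints
arise, and an unrounded r can be passed instead.

## Synthetic cohorts

`CohortSpec` defaults are the emulated study conditions: n = 42 analyzable
subjects, 25/42 assigned to immediate CBT, baseline LSAS ~ N(82.0, 17.9²)
clipped to the scale range [0, 144], post-CBT mean 51.3 and SD 24.2, baseline
explaining 20% of change-score variance. The change score is generated as

    Δ = μ_Δ + a·(baseline − μ_b) + c·conn + ε,

with a and c scaled so baseline and the latent composite carry exactly the
requested population variance fractions. The SD of Δ is *derived* from the
baseline/post SDs and r2_baseline by solving
Var(post) = σ_b² + σ_Δ² − 2·√(r2_b)·σ_b·σ_Δ for σ_Δ (≈ 26.2 under the
defaults), which implies a generating baseline slope of ≈ 0.653 — consistent
with the cohort-level OLS slopes this design should produce (0.62–0.66). The
latent composite is drawn N(0, 0.15²) clipped to (−0.9, 0.9); its real-world
distribution is unknown, so the SD is a stand-in exposed as `conn_sd`.
The default incremental connectivity effect is 2% of variance (the
replication-scale condition); 21% reproduces the derivation-scale condition.

Post scores are clipped to [0, 144] after the Gaussian draw and Δ is
recomputed from the clipped value, so the record invariant Δ = baseline −
post holds exactly; the mild censoring this introduces (≈1.7% of subjects at
the floor under defaults) perturbs the recovered variance fractions by well
under the ±0.01 tolerance the tests allow at n = 10⁵. Interim LSAS measures
interpolate linearly toward the latent endpoint with 3-point noise; only the
last-observation-carried-forward endpoint matters downstream. Dropouts
(default rate 0) get a truncated series and fewer than 12 of 16 sessions, so
the eligibility filter removes them. The default dropout rate is 0 because
the emulated n ≈ 42 is the *post*-eligibility analyzed sample.

## Synthetic scans

Each subject's five neural ROI signals are unit-variance Gaussian series
colored by the Cholesky factor of a 5×5 target correlation matrix: seed-to-
positive-cluster correlation +t, seed-to-negative-cluster −t (under the
default sign convention), cluster–cluster 0, where t is the subject's latent
composite. For |t| ≥ 0.5 the target is indefinite and is repaired by
eigenvalue clipping with diagonal renormalization (the realized composite
then shrinks; draws at SD 0.15 essentially never reach this regime). On top
of the signal go: a 0.005 Hz sinusoid-plus-trend drift, three smooth AR(1)
"physiological" components shared with the WM/CSF compartments (positive
loadings, so the raw composite is genuinely biased), and motion-locked
intensity spikes paired with step jumps in the motion parameters. Voxels are
the ROI signal plus iid noise (SD 0.1 over ~20 voxels, so attenuation of the
mean-series correlations is negligible). A scan is 200 volumes at TR = 1.5 s
by default; per-subject RNG streams fold a CRC32 of the subject id into the
scan seed so cohorts are reproducible subject by subject.

## Denoising

- **FD**: Power-style sum of absolute backward differences, rotations
  converted at a configurable 50 mm radius; fd[0] = 0, summaries over fd[1:].
- **Spike flagging**: per-parameter backward differences (rotations converted
  to mm) against the 0.5 mm threshold — the conservative per-direction
  reading of "displacement in any direction"; a composite-displacement
  variant is selectable. Intensity flags use the two-sided |z| ≥ 3 rule on
  the global signal, z-scored with the sample SD (ddof = 1). The first volume
  is never motion-flagged.
- **aCompCor**: each compartment's voxel time courses are temporally
  demeaned and the top-k right-singular vectors (k = 3 per compartment by
  default; a pooled variant exists) enter the design, orthonormal and
  variance-ordered.
- **Nuisance GLM**: 6 motion + 6 backward-difference derivatives (leading
  zero row) + tissue components + one indicator per flagged volume, intercept
  always included; constant-zero columns are dropped and residual rank
  deficiency is an error naming the offending columns.
- **Band-pass**: ideal rectangular DFT filter keeping frequencies strictly
  inside (0.01, 0.10) Hz, no padding; DC is always removed.
- **Order**: regress, then filter — with the design columns themselves
  band-pass filtered before the regression. This makes the regress+filter
  pair one orthogonal projection (onto the in-band subspace orthogonal to the
  band-limited nuisance), hence exactly idempotent, and prevents the filter
  from reintroducing components of regressed-out nuisance — the standard
  argument for simultaneous nuisance regression and filtering. Spike
  censoring is correspondingly band-limited: it removes the flagged volumes'
  in-band artifact content rather than literally zeroing samples.

## Connectivity composite

Correlations are averaged **before** the Fisher transform (the marker's
definition), with a per-correlation-transform variant behind a flag for
sensitivity analysis. The default sign convention flips the negative-cluster
correlations so that reduced connectivity with those clusters raises the
composite — required for the frozen positive coefficient to point in the
documented direction; a `raw` averaging mode is retained. Likewise the
1-vs-3 weighting is mean-of-four by default with a two-group average behind
a flag, since the exact arithmetic is a convention. Cohort z-scoring uses
ddof = 1. Masks/ROI grids must match exactly; no resampling is attempted.

## Problem sizes and observed behavior

The test suite and `scripts/acceptance.py` use: 1000 random instances for
the metric oracles; 6! exhaustive permutations; 500 null cohorts × 999
permutations for type-I calibration; 200 cohorts per planted-effect
condition. These sizes put Monte-Carlo error comfortably inside the asserted
bands while keeping a full run in the low minutes on one CPU.

One consequence of frozen-coefficient validation is worth flagging: under
the small (2%) planted effect the frozen β_c = 8.629 per SD is larger than
the generating per-SD effect (≈ 3.7), so the *population* prediction R² of
the frozen full model is slightly negative (≈ −0.02) and the mean
model-based ΔR² near zero, even though the effect is real — an oversized
frozen coefficient adds error variance faster than signal. The workflow
reports exactly this, and the permutation test still rejects more often than
α (the unpermuted term carries the covariance). Under the 21% condition the
frozen coefficient is close to the generating one and mean ΔR² recovers
≈ 0.20.

## Limitations

Simulated scans are ROI-level: no image-space preprocessing (realignment,
normalization, smoothing) is modeled, motion parameters are consumed as
given, and voxel noise is iid — so passing tests demonstrate the statistical
pipeline's correctness, not robustness to spatially structured artifacts.
The latent composite's distribution (SD 0.15) is a modeling choice, not an
estimate. LSAS clipping is a crude account of scale boundaries. The
flexible GLM uses classical (non-robust) standard errors by design, matching
the t(n−3) convention of the analysis it mirrors.
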