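# amygconn

Toolkit for externally validating a **fixed resting-state amygdala-connectivity
marker** of cognitive-behavioral-therapy (CBT) response in social anxiety
disorder — and for studying, by simulation, how such a validation behaves at
realistic sample sizes.

## The problem

A predictive brain marker is only useful if its *frozen* form — coefficients
and all — keeps predicting in new data. The marker implemented here predicts
treatment response (the pre-to-post change in the Liebowitz Social Anxiety
Scale, ΔLSAS = baseline − post, positive = improvement) from baseline severity
plus a composite of seed-based amygdala connectivity:

```
ΔLSAS = 0.6194 · baseline_LSAS + 8.6290 · amyg_conn − 9.9763
```

`amyg_conn` is built per subject from denoised ROI time series: Pearson
correlations of the amygdala seed's mean time course with one positively
weighted cluster (subgenual cingulate/caudate/putamen) and three negatively
weighted clusters (bilateral central sulcus, right temporal-occipital) are
signed-averaged into one composite, Fisher-transformed (arctanh), and z-scored
across subjects. For external validation the model is applied in mean-centered
form without the intercept (intercept effects vary from study to study); the
coefficients are never re-fit.

Performance is scored against a **compact model** (baseline term only) with two
metrics:

- **prediction R²** = 1 − MSE(full)/MSE(compact), the proportional reduction in
  squared error (can be negative);
- **model-based R²** = squared correlation between observed outcomes and each
  model's predictions, reported as the full-minus-compact difference.

Significance comes from a permutation test that shuffles only the connectivity
term across subjects (baseline–outcome pairs stay intact), recomputing the
metric with the frozen coefficients for each shuffle.

The package covers the whole workflow: a synthetic-cohort and ROI-scan
generator with *planted* effects (so every stage is testable without patient
data), Conn-style denoising (motion + derivative regressors, aCompCor tissue
components, 0.5 mm / 3 SD spike flagging, 0.01–0.10 Hz band-pass, framewise
displacement), the connectivity composite, the frozen/compact/flexible models,
the metric and permutation machinery, and the closed-form power and
confidence-interval computations for correlation effect sizes.

## Worked example

`examples/03_run_replication.py` simulates a 42-subject cohort in which the
connectivity composite carries 2% of the outcome variance beyond baseline
(the replication-scale condition) and runs the full workflow:

```
analyzed subjects: 42
prediction R^2 = -0.0064   (permutation p = 0.158)
model-based R^2: full 0.4111, compact 0.4720, delta -0.0610 (p = 0.101)
flexible GLM: beta_amyg_conn = 5.97, t(39) = 1.61, p = 0.12
frozen-vs-OLS baseline slope, prediction R^2 = 0.1757
```

Read: adding the connectivity term to the frozen model barely changes squared
error (prediction R² ≈ −0.006) and does not reach significance against the
permutation null; the flexible re-fit of the same terms is likewise
non-significant at this sample size. With a planted 21% effect at N = 38
(`CohortSpec(n_subjects=38, r2_conn_incremental=0.21)`) the same workflow
rejects in ~95% of cohorts — the contrast between a well-powered derivation
and an underpowered validation.

The other examples show cohort variance-fraction recovery
(`01_simulate_cohort.py`), denoising pulling a corrupted composite back to its
planted value (`02_denoise_and_connectivity.py`), and the design computations
(`04_power_and_ci.py`): the two-tailed Fisher-z test of ρ = 0.3 at n = 40 has
46.9% power, and 21% variance explained at N = 38 carries a 95% CI of 2.7% to
46.2%.

A thin CLI wraps the same stages:

```bash
amygconn power --rho 0.3 --n 40
amygconn ci --r 0.46 --n 38
amygconn replicate --config demo.yaml --out results/
```

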