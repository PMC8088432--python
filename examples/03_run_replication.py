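"""Run the full replication workflow on a simulated cohort.

The cohort plants a small (2% of variance) incremental connectivity effect
at n = 42 — the replication-scale condition.  The frozen model is applied in
its centered form, scored against the baseline-only compact model, and
tested by permuting the connectivity term (10,000 shuffles).
"""

from amygconn import CohortSpec, run_replication, simulate_clinical_cohort

cohort = simulate_clinical_cohort(CohortSpec(n_subjects=42, r2_conn_incremental=0.02, seed=6))
report = run_replication(cohort, n_perms=10_000, seed=0)

m, gp = report.metrics, report.glm
print(f"analyzed subjects: {report.n_analyzed}")
print(f"prediction R^2 = {m.prediction_r2:+.4f}   (permutation p = {report.perm_prediction.p_value:.3f})")
print(f"model-based R^2: full {m.r2_full:.4f}, compact {m.r2_compact:.4f}, "
      f"delta {m.delta_model_r2:+.4f} (p = {report.perm_delta_model.p_value:.3f})")
print(f"flexible GLM: beta_amyg_conn = {gp.betas[2]:.2f}, t({gp.dof}) = {gp.tvals[2]:.2f}, "
      f"p = {gp.pvals[2]:.2f}")
print(f"frozen-vs-OLS baseline slope, prediction R^2 = {report.beta_comparison:.4f}")
print("With only 2% planted incremental variance the connectivity term adds little "
      "and the permutation test rarely reaches significance — the underpowered-replication regime.")
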