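"""Scoring, permutation inference and the end-to-end replication workflow.

Two complementary metrics compare the frozen full model against the compact
baseline-only benchmark:

* prediction R² = 1 − NMSE, where NMSE = MSE(full)/MSE(compact) — the
  proportional reduction in squared prediction error, an absolute measure
  that can go negative when the connectivity term hurts;
* model-based R² — squared Pearson correlation between observed outcomes and
  each model's predictions, a scale-free measure, reported as the difference
  full − compact.

Significance comes from a permutation test that shuffles only the
connectivity term across subjects (baseline–outcome pairings stay intact),
recomputing the metric with the frozen coefficients for each shuffle.  The
module also carries the self-contained design computations: two-tailed power
of the Fisher-z correlation test and Fisher-z confidence intervals for
variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .cohort import SubjectRecord, apply_locf, eligible_subjects
from .connectivity import fisher_z, zscore_across_subjects
from .model import FixedModelSpec, GlmFit, compare_beta_sources, fit_ols

__all__ = [
    "EvalMetrics",
    "PermutationResult",
    "PowerQuery",
    "ReplicationReport",
    "prediction_r2",
    "model_based_r2",
    "evaluate_predictions",
    "permutation_test",
    "run_replication",
    "check_normality",
    "correlation_power",
    "r2_confidence_interval",
]


@dataclass
class EvalMetrics:
    mse_full: float | None = None
    mse_compact: float | None = None
    nmse: float | None = None
    prediction_r2: float | None = None
    r2_full: float | None = None
    r2_compact: float | None = None
    delta_model_r2: float | None = None


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    n_perms: int
    p_value: float
    seed: int
    crit95: float
    n_redrawn: int = 0


@dataclass(frozen=True)
class PowerQuery:
    rho: float
    n: int
    alpha: float = 0.05
    level: float = 0.95

    def validate(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        for name in ("alpha", "level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def _check_vectors(*vecs) -> tuple:
    arrs = [np.asarray(v, dtype=float) for v in vecs]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise ValueError("all vectors must share one length")
    if n < 2:
        raise ValueError("need at least 2 observations")
    return tuple(arrs)


def prediction_r2(observed, full_pred, compact_pred) -> EvalMetrics:
    """1 − NMSE: proportional reduction in squared error over the compact model."""
    obs, full, compact = _check_vectors(observed, full_pred, compact_pred)
    mse_full = float(np.mean((obs - full) ** 2))
    mse_compact = float(np.mean((obs - compact) ** 2))
    if mse_compact == 0:
        raise ValueError("compact model fits perfectly; NMSE undefined")
    nmse = mse_full / mse_compact
    return EvalMetrics(
        mse_full=mse_full, mse_compact=mse_compact, nmse=nmse, prediction_r2=1.0 - nmse
    )


def model_based_r2(observed, full_pred, compact_pred) -> EvalMetrics:
    """Squared observed-vs-predicted correlations and their difference."""
    obs, full, compact = _check_vectors(observed, full_pred, compact_pred)
    for name, v in (("observed", obs), ("full_pred", full), ("compact_pred", compact)):
        if v.std() == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    r2_full = float(np.corrcoef(obs, full)[0, 1] ** 2)
    r2_compact = float(np.corrcoef(obs, compact)[0, 1] ** 2)
    return EvalMetrics(
        r2_full=r2_full, r2_compact=r2_compact, delta_model_r2=r2_full - r2_compact
    )


def evaluate_predictions(observed, full_pred, compact_pred) -> EvalMetrics:
    """Both metric families on one set of predictions."""
    a = prediction_r2(observed, full_pred, compact_pred)
    b = model_based_r2(observed, full_pred, compact_pred)
    a.r2_full, a.r2_compact, a.delta_model_r2 = b.r2_full, b.r2_compact, b.delta_model_r2
    return a


def _rowwise_corr(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ vc) / denom


def _metric_rows(
    conn_rows: np.ndarray,
    baseline_c: np.ndarray,
    observed_c: np.ndarray,
    spec: FixedModelSpec,
    metric: str,
) -> np.ndarray:
    """Metric values for many candidate connectivity vectors at once (centered path)."""
    pred_compact = spec.beta_baseline * baseline_c
    resid_compact = observed_c - pred_compact
    mse_compact = float(np.mean(resid_compact**2))
    if metric == "prediction_r2":
        if mse_compact == 0:
            raise ValueError("compact model fits perfectly; NMSE undefined")
        mse_full = np.mean((resid_compact[None, :] - spec.beta_conn * conn_rows) ** 2, axis=1)
        return 1.0 - mse_full / mse_compact
    if metric == "delta_model_r2":
        pred_full = pred_compact[None, :] + spec.beta_conn * conn_rows
        r_full = _rowwise_corr(pred_full, observed_c)
        r_compact = _rowwise_corr(pred_compact[None, :], observed_c)[0]
        return r_full**2 - r_compact**2
    raise ValueError(f"unknown metric: {metric!r}")


def permutation_test(
    baseline_centered,
    conn_z,
    observed_centered,
    spec: FixedModelSpec = FixedModelSpec(),
    metric: str = "prediction_r2",
    n_perms: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution from shuffling the connectivity term across subjects.

    Baseline and outcome stay paired; only ``conn_z`` is permuted, and the
    full-model predictions are recomputed with the frozen coefficients for
    every shuffle.  The p-value uses the add-one estimator
    (1 + #{null ≥ observed}) / (1 + n_perms); ``crit95`` is the null's 95th
    percentile.  Permutations on which the metric is undefined (degenerate
    variance) are redrawn and counted.  Deterministic given ``seed``.
    """
    bc, cz, oc = _check_vectors(baseline_centered, conn_z, observed_centered)
    if bc.size < 5:
        raise ValueError("need >= 5 subjects for permutation inference")
    if n_perms < 99:
        raise ValueError("n_perms must be >= 99")
    rng = np.random.default_rng(seed)
    observed_stat = float(_metric_rows(cz[None, :], bc, oc, spec, metric)[0])
    perms = rng.permuted(np.broadcast_to(cz, (n_perms, cz.size)).copy(), axis=1)
    null = _metric_rows(perms, bc, oc, spec, metric)
    n_redrawn = 0
    bad = ~np.isfinite(null)
    while bad.any():
        n_redrawn += int(bad.sum())
        redraw = rng.permuted(np.broadcast_to(cz, (int(bad.sum()), cz.size)).copy(), axis=1)
        null[bad] = _metric_rows(redraw, bc, oc, spec, metric)
        bad = ~np.isfinite(null)
    p = (1.0 + float((null >= observed_stat).sum())) / (1.0 + n_perms)
    return PermutationResult(
        observed_stat=observed_stat,
        null_stats=null,
        n_perms=n_perms,
        p_value=p,
        seed=seed,
        crit95=float(np.percentile(null, 95.0)),
        n_redrawn=n_redrawn,
    )


def check_normality(values) -> tuple[float, float]:
    """Anderson–Darling composite normality test (mean and variance estimated)."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8 for the Anderson-Darling normality test")
    stat, p = normal_ad(x)
    return float(stat), float(p)


def correlation_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Two-tailed power of the Fisher-z test of a Pearson correlation.

    With λ = arctanh(ρ)·√(n−3), power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2});
    at ρ = 0 this reduces to the test's size α.
    """
    PowerQuery(rho=rho, n=n, alpha=alpha).validate()
    lam = np.arctanh(rho) * np.sqrt(n - 3)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(lam - zcrit) + stats.norm.cdf(-lam - zcrit))


def r2_confidence_interval(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for variance explained, in percent.

    The interval arctanh(r) ± z_{(1+level)/2}/√(n−3) is back-transformed by
    tanh and the endpoints squared; if the correlation interval straddles
    zero, the lower bound on variance explained is 0.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie in (0, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    half = stats.norm.ppf((1.0 + level) / 2.0) / np.sqrt(n - 3)
    lo_r = np.tanh(np.arctanh(r) - half)
    hi_r = np.tanh(np.arctanh(r) + half)
    lo = 0.0 if lo_r < 0 else float(100.0 * lo_r**2)
    hi = float(100.0 * hi_r**2)
    return lo, hi


@dataclass
class ReplicationReport:
    subset: str
    n_total: int
    n_eligible: int
    n_analyzed: int
    model: FixedModelSpec
    metrics: EvalMetrics
    perm_prediction: PermutationResult
    perm_delta_model: PermutationResult
    normality: dict
    glm: GlmFit
    beta_comparison: float
    seed: int

    def summary(self) -> dict:
        """JSON-ready digest (null distributions reduced to summaries)."""
        def perm(p: PermutationResult) -> dict:
            return {
                "observed": p.observed_stat,
                "p_value": p.p_value,
                "crit95": p.crit95,
                "null_mean": float(np.mean(p.null_stats)),
                "null_sd": float(np.std(p.null_stats, ddof=1)),
                "n_perms": p.n_perms,
                "n_redrawn": p.n_redrawn,
            }

        return {
            "subset": self.subset,
            "n_total": self.n_total,
            "n_eligible": self.n_eligible,
            "n_analyzed": self.n_analyzed,
            "coefficients": {
                "beta_baseline": self.model.beta_baseline,
                "beta_conn": self.model.beta_conn,
                "intercept": self.model.intercept,
                "centered": self.model.centered,
            },
            "prediction_r2": self.metrics.prediction_r2,
            "nmse": self.metrics.nmse,
            "model_based_r2_full": self.metrics.r2_full,
            "model_based_r2_compact": self.metrics.r2_compact,
            "delta_model_r2": self.metrics.delta_model_r2,
            "permutation": {
                "prediction_r2": perm(self.perm_prediction),
                "delta_model_r2": perm(self.perm_delta_model),
            },
            "normality_ad": {k: {"stat": v[0], "p": v[1]} for k, v in self.normality.items()},
            "flexible_glm": {
                "names": self.glm.names,
                "betas": self.glm.betas.tolist(),
                "tvals": self.glm.tvals.tolist(),
                "pvals": self.glm.pvals.tolist(),
                "dof": self.glm.dof,
            },
            "frozen_vs_ols_baseline_prediction_r2": self.beta_comparison,
            "seed": self.seed,
        }


def run_replication(
    cohort: list[SubjectRecord],
    spec: FixedModelSpec = FixedModelSpec(),
    conn_values: dict | None = None,
    subset: str = "all",
    n_perms: int = 10_000,
    seed: int = 0,
    min_sessions: int = 12,
) -> ReplicationReport:
    """The full replication workflow on one cohort.

    Eligibility filter (≥ ``min_sessions`` of 16 sessions) → LOCF endpoint →
    optional restriction to the CBT-immediate subset → Fisher transform and
    cohort z-scoring of the composite connectivity values → centered
    fixed-coefficient predictions → both metrics → a permutation test per
    metric, plus normality checks, the flexible re-estimated GLM and the
    frozen-vs-OLS baseline-slope comparison.

    ``conn_values`` maps subject id to the raw composite connectivity (as
    produced by the connectivity stage); if omitted, the simulation ground
    truth ``true_composite_conn`` is used.
    """
    if subset not in ("all", "immediate_only"):
        raise ValueError(f"unknown subset: {subset!r}")
    elig = eligible_subjects(cohort, min_sessions=min_sessions)
    analyzed = [r for r in elig if subset == "all" or r.group == "immediate"]
    if len(analyzed) < 5:
        raise ValueError(f"only {len(analyzed)} analyzable subjects; need >= 5")
    analyzed = sorted(analyzed, key=lambda r: r.subject_id)

    baseline = np.array([r.baseline_lsas for r in analyzed])
    post = np.array([apply_locf(r.lsas_series) for r in analyzed])
    delta = baseline - post
    if conn_values is None:
        raw_conn = np.array([r.true_composite_conn for r in analyzed])
    else:
        raw_conn = np.array([conn_values[r.subject_id] for r in analyzed])
    conn_z = zscore_across_subjects(fisher_z(raw_conn))

    if spec.centered:
        bc = baseline - baseline.mean()
        oc = delta - delta.mean()
    else:
        bc, oc = baseline, delta
    from .model import predict_compact, predict_fixed

    pred_full = predict_fixed(spec, bc, conn_z)
    pred_compact = predict_compact(spec, bc)
    metrics = evaluate_predictions(oc, pred_full, pred_compact)

    ss = np.random.SeedSequence(seed).spawn(2)
    perm_pred = permutation_test(
        bc, conn_z, oc, spec, "prediction_r2", n_perms, int(ss[0].generate_state(1)[0] % 2**31)
    )
    perm_delta = permutation_test(
        bc, conn_z, oc, spec, "delta_model_r2", n_perms, int(ss[1].generate_state(1)[0] % 2**31)
    )

    normality = {}
    if len(analyzed) >= 8:
        for name, vec in (("baseline_lsas", baseline), ("amyg_conn", conn_z), ("delta_lsas", delta)):
            normality[name] = check_normality(vec)

    glm = fit_ols(delta, np.column_stack([baseline, conn_z]), names=["baseline_lsas", "amyg_conn"])
    beta_cmp = compare_beta_sources(baseline, delta, frozen_beta=spec.beta_baseline)

    return ReplicationReport(
        subset=subset,
        n_total=len(cohort),
        n_eligible=len(elig),
        n_analyzed=len(analyzed),
        model=spec,
        metrics=metrics,
        perm_prediction=perm_pred,
        perm_delta_model=perm_delta,
        normality=normality,
        glm=glm,
        beta_comparison=beta_cmp,
        seed=seed,
    )
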