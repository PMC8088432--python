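"""The frozen predictive model and its flexible re-estimated counterpart.

The marker's prediction of treatment response (ΔLSAS, baseline − post) is a
fixed linear rule

    ΔLSAS = 0.6194 * baseline_LSAS + 8.6290 * amyg_conn − 9.9763

whose coefficients were estimated once in the original derivation cohort and
are *never* re-fit here.  External validation drops the intercept and
mean-centers all variables in the validation cohort (intercept effects vary
study to study), so the centered variant predicts

    ΔLSAS_c = 0.6194 * baseline_c + 8.6290 * amyg_conn

with amyg_conn already mean-zero by cohort standardization.  The compact
benchmark uses the baseline term alone.  A separate, clearly flexible OLS
pathway re-estimates the same terms for the "did the term reach
significance" check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm

__all__ = [
    "FixedModelSpec",
    "ORIGINAL_MODEL",
    "ModelPredictions",
    "GlmFit",
    "predict_fixed",
    "predict_compact",
    "fit_ols",
    "compare_beta_sources",
]


@dataclass(frozen=True)
class FixedModelSpec:
    """Frozen coefficients of the original predictive model."""

    beta_baseline: float = 0.6194  # ΔLSAS per baseline LSAS point
    beta_conn: float = 8.6290  # ΔLSAS per SD of amyg_conn
    intercept: float = -9.9763  # ΔLSAS points; unused when centered
    centered: bool = True


#: The original report's model, exactly as published (uncentered form).
ORIGINAL_MODEL = FixedModelSpec(centered=False)


@dataclass
class ModelPredictions:
    full: np.ndarray
    compact: np.ndarray
    observed: np.ndarray
    centered: bool


@dataclass
class GlmFit:
    names: list
    betas: np.ndarray
    ses: np.ndarray
    tvals: np.ndarray
    dof: int
    pvals: np.ndarray


def predict_fixed(spec: FixedModelSpec, baseline_lsas, amyg_conn) -> np.ndarray:
    """Evaluate the frozen full model.

    In centered mode the inputs must already be cohort-centered and no
    intercept is added; in uncentered mode the published intercept applies.
    """
    b = np.asarray(baseline_lsas, dtype=float)
    c = np.asarray(amyg_conn, dtype=float)
    pred = spec.beta_baseline * b + spec.beta_conn * c
    if not spec.centered:
        pred = pred + spec.intercept
    return pred


def predict_compact(spec: FixedModelSpec, baseline_lsas) -> np.ndarray:
    """The compact benchmark: the full model with amyg_conn forced to zero."""
    return predict_fixed(spec, baseline_lsas, np.zeros_like(np.asarray(baseline_lsas, dtype=float)))


def fit_ols(outcome, regressors, names: list | None = None) -> GlmFit:
    """Ordinary least squares with an intercept and classical standard errors.

    ``regressors`` is an (n, p) array (or 1-D for a single slope).  Two-tailed
    p-values come from the t distribution on n − (p + 1) degrees of freedom.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations to fit {p} slopes plus intercept")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("regressor matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    return GlmFit(
        names=["intercept"] + list(names),
        betas=np.asarray(res.params),
        ses=np.asarray(res.bse),
        tvals=np.asarray(res.tvalues),
        dof=int(res.df_resid),
        pvals=np.asarray(res.pvalues),
    )


def compare_beta_sources(baseline_lsas, delta_lsas, frozen_beta: float = 0.6194) -> float:
    """Prediction R² of the cohort-OLS compact model relative to the frozen one.

    Both compact models are evaluated in centered space (slope times centered
    baseline vs. centered outcome); the return value 1 − MSE_ols/MSE_frozen
    is the proportional error reduction from re-estimating the baseline
    slope.  Near zero means the frozen slope transfers well.
    """
    b = np.asarray(baseline_lsas, dtype=float)
    d = np.asarray(delta_lsas, dtype=float)
    bc = b - b.mean()
    dc = d - d.mean()
    denom = float(bc @ bc)
    if denom == 0:
        raise ValueError("baseline has zero variance")
    beta_ols = float(bc @ dc) / denom
    mse_frozen = float(np.mean((dc - frozen_beta * bc) ** 2))
    mse_ols = float(np.mean((dc - beta_ols * bc) ** 2))
    if mse_frozen == 0:
        raise ValueError("frozen compact model fits perfectly; comparison undefined")
    return 1.0 - mse_ols / mse_frozen
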