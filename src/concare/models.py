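"""Logistic association models between continuity category and utilization.

The exposure is the median-cut continuity category with **high
continuity as the reference**, so an odds ratio above 1 means low
continuity is associated with more unplanned utilization. Three
adjustment tiers mirror the usual confounder build-up:

* ``unadjusted`` — exposure only;
* ``model_A``    — age, sex, comorbidity (ADG score), socioeconomic
  status (income quintile + marginalization composite) and rurality;
* ``model_B``    — Model A plus the predominant provider group.

Fits are maximum-likelihood logistic regressions (statsmodels) with
Wald 95% intervals ``exp(beta +/- 1.96 SE)``; perfect separation or
non-convergence is reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError

Z_95 = 1.959963984540054

OUTCOME_COLUMNS = {
    "any_admission": "any_admission",
    "any_ed_visit": "n_ed_all",
    "any_readmission_30d": "any_readmission_30d",
    "multiple_readmissions": "n_readmissions_30d",
}
TIERS = ("unadjusted", "model_A", "model_B")

MODEL_A_COVARIATES = (
    "age_at_index",
    "sex_m",
    "adg_score",
    "income_quintile",
    "marginalization_composite",
    "rural",
)
MODEL_B_COVARIATES = MODEL_A_COVARIATES + ("predominant_group",)


@dataclass(frozen=True)
class ModelSpec:
    """One model of the suite: outcome x adjustment tier."""

    outcome: str
    adjustment_tier: str = "unadjusted"
    exposure: str = "low_coci"
    reference: str = "high"

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise ModelError(f"unknown outcome '{self.outcome}'")
        if self.adjustment_tier not in TIERS:
            raise ModelError(f"unknown adjustment tier '{self.adjustment_tier}'")

    @property
    def covariates(self) -> tuple:
        if self.adjustment_tier == "unadjusted":
            return ()
        if self.adjustment_tier == "model_A":
            return MODEL_A_COVARIATES
        return MODEL_B_COVARIATES


@dataclass
class ModelResult:
    """Exposure OR with Wald 95% CI and the fitted coefficient set."""

    spec: ModelSpec
    coefficients: dict
    standard_errors: dict
    exposure_or: float
    ci95: tuple
    n_used: int
    converged: bool

    def to_row(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "tier": self.spec.adjustment_tier,
            "odds_ratio": self.exposure_or,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "n_used": self.n_used,
            "converged": self.converged,
        }


def _outcome_vector(outcomes: pd.DataFrame, name: str) -> pd.Series:
    col = OUTCOME_COLUMNS[name]
    if name == "any_ed_visit":
        return (outcomes[col] >= 1).astype(int)
    if name == "multiple_readmissions":
        # "number of readmissions" operationalized as >= 2 vs < 2, fitted
        # with the same logistic machinery as the other outcomes.
        return (outcomes[col] >= 2).astype(int)
    return outcomes[col].astype(bool).astype(int)


def build_design(
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    persons: pd.DataFrame,
    spec: ModelSpec,
) -> tuple[pd.Series, pd.DataFrame]:
    """Model-ready response and design matrix for one spec.

    ``persons`` is the analysis covariate table: the person registry
    joined with the cohort's ``age_at_index``. Patients whose continuity
    was not assessed (<= 5 visits) are dropped. Categorical covariates
    expand against fixed reference levels (income quintile 1, FP
    provider group, female sex, high continuity).
    """
    data = (
        profiles[profiles["coci_category"].isin(["low", "high"])]
        .merge(outcomes, on="patient_id")
        .merge(persons, on="patient_id", how="inner")
    )
    y = _outcome_vector(data, spec.outcome)
    X = pd.DataFrame(index=data.index)
    X[spec.exposure] = (data["coci_category"] == "low").astype(float)
    for cov in spec.covariates:
        if cov == "sex_m":
            X["sex_m"] = (data["sex"] == "M").astype(float)
        elif cov == "income_quintile":
            for q in (2, 3, 4, 5):  # quintile 1 is the reference
                X[f"income_q{q}"] = (data["income_quintile"] == q).astype(float)
        elif cov == "predominant_group":
            X["provider_sp"] = (data["predominant_group"] == "SP").astype(float)
        elif cov == "rural":
            X["rural"] = data["rural"].astype(bool).astype(float)
        else:
            X[cov] = data[cov].astype(float)
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ModelError(f"covariate '{col}' has a single level in the design")
    return y, X


def fit_logistic(
    y: pd.Series, X: pd.DataFrame, exposure: str = "low_coci", spec: ModelSpec | None = None
) -> ModelResult:
    """Maximum-likelihood logistic fit with Wald 95% CI on the exposure."""
    if y.nunique() < 2:
        raise ModelError("outcome has a single level; cannot fit")
    design = sm.add_constant(X, has_constant="add")
    spec = spec or ModelSpec("any_admission")
    converged = True
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(np.asarray(y, dtype=float), design).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return ModelResult(
            spec=spec,
            coefficients={},
            standard_errors={},
            exposure_or=float("nan"),
            ci95=(float("nan"), float("nan")),
            n_used=int(len(y)),
            converged=False,
        )
    params = dict(zip(design.columns, fit.params))
    bse = dict(zip(design.columns, fit.bse))
    beta = params[exposure]
    se = bse[exposure]
    with np.errstate(over="ignore"):
        odds_ratio = float(np.exp(beta))
        ci = (float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se)))
    return ModelResult(
        spec=spec,
        coefficients=params,
        standard_errors=bse,
        exposure_or=odds_ratio,
        ci95=ci,
        n_used=int(len(y)),
        converged=converged,
    )


def fit_model(
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    persons: pd.DataFrame,
    spec: ModelSpec,
) -> ModelResult:
    y, X = build_design(profiles, outcomes, persons, spec)
    return fit_logistic(y, X, exposure=spec.exposure, spec=spec)


def run_model_suite(
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    persons: pd.DataFrame,
) -> tuple[pd.DataFrame, list[ModelResult]]:
    """Fit all 4 outcomes x 3 adjustment tiers (12 models, fixed order)."""
    results = []
    for outcome in OUTCOME_COLUMNS:
        for tier in TIERS:
            spec = ModelSpec(outcome=outcome, adjustment_tier=tier)
            try:
                results.append(fit_model(profiles, outcomes, persons, spec))
            except ModelError as exc:
                raise ModelError(f"{outcome}/{tier}: {exc}") from exc
    table = pd.DataFrame([r.to_row() for r in results])
    return table, results
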