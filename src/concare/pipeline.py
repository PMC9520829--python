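"""End-to-end convenience pipeline: tables -> cohort -> profiles ->
outcomes -> model suite."""

from __future__ import annotations

from types import SimpleNamespace

import pandas as pd

from .cohort import (
    DEFAULT_RECRUITMENT_WINDOW,
    DEFAULT_STUDY_END,
    CaseDefinition,
    build_cohort,
)
from .continuity import compute_profiles
from .models import run_model_suite
from .outcomes import summarize_utilization


def covariate_table(persons: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Person registry joined with cohort index-date covariates, the
    input the model suite expects."""
    return persons.merge(
        cohort.loc[cohort["eligible"].astype(bool), ["patient_id", "age_at_index"]],
        on="patient_id",
        how="inner",
    )


def run_pipeline(
    tables: dict,
    case_def: CaseDefinition | None = None,
    recruitment_window=DEFAULT_RECRUITMENT_WINDOW,
    study_end: str = DEFAULT_STUDY_END,
    fit_models: bool = True,
    unplanned_only: bool = False,
) -> SimpleNamespace:
    """Run cohort derivation, continuity profiling, outcome derivation
    and (optionally) the 12-model association suite.

    Returns a namespace with ``cohort``, ``profiles``, ``outcomes``,
    ``covariates`` and, when ``fit_models``, ``suite`` (a 12-row table)
    and ``results`` (the ModelResult objects).
    """
    case_def = case_def or CaseDefinition()
    cohort = build_cohort(
        tables,
        case_def=case_def,
        recruitment_window=recruitment_window,
        study_end=study_end,
    )
    profiles = compute_profiles(
        tables["claims"],
        cohort,
        persons=tables.get("persons"),
        providers=tables.get("providers"),
    )
    outcomes = summarize_utilization(
        tables["discharges"],
        tables["ed_visits"],
        cohort,
        copd_code_sets=case_def,
        unplanned_only=unplanned_only,
    )
    out = SimpleNamespace(
        cohort=cohort,
        profiles=profiles,
        outcomes=outcomes,
        covariates=covariate_table(tables["persons"], cohort),
    )
    if fit_models:
        out.suite, out.results = run_model_suite(profiles, outcomes, out.covariates)
    return out
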