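"""Unplanned healthcare-utilization outcomes over follow-up.

Per eligible patient: all-cause and COPD-related admission counts,
30-day readmissions, ED visit classes (with / without admission,
COPD-related) and in-hospital death, all restricted to the half-open
follow-up interval ``[index_date, followup_end)``.

Conventions (documented where the source databases are silent):

* Overlapping or nested hospital stays are merged into one episode
  before any counting, so transfers-back cannot create artifactual
  0-day readmissions.
* A 30-day readmission is a non-elective, non-transfer admission whose
  admit date lies in ``(discharge, discharge + 30 days]`` of the
  immediately preceding episode — inclusive of day 30, exclusive of
  day 0.
* "COPD-related" means the most-responsible diagnosis matches the
  case-definition code sets (prefix match).
* A scheduled ED-to-admission encounter is planned care and is excluded
  from the ED counts entirely.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import CaseDefinition

logger = logging.getLogger(__name__)

BIN_LABELS = ("0", "1 to 5", "6 to 10", "> 10")
READMISSION_WINDOW_DAYS = 30
NON_UNPLANNED_CATEGORIES = ("elective", "transfer")


def bin_counts(count: int) -> str:
    """Bin a utilization count into the reporting categories
    {0, 1 to 5, 6 to 10, > 10}."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return BIN_LABELS[0]
    if count <= 5:
        return BIN_LABELS[1]
    if count <= 10:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def bin_series(counts: pd.Series) -> pd.Series:
    """Vectorized :func:`bin_counts` preserving the category order."""
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    binned = pd.cut(
        counts,
        bins=[-0.5, 0.5, 5.5, 10.5, np.inf],
        labels=list(BIN_LABELS),
    )
    return binned.astype(pd.CategoricalDtype(list(BIN_LABELS), ordered=True))


def _eligible(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort[cohort["eligible"].astype(bool)][
        ["patient_id", "index_date", "followup_end"]
    ].copy()
    out["index_date"] = pd.to_datetime(out["index_date"])
    out["followup_end"] = pd.to_datetime(out["followup_end"])
    return out


def merge_episodes(discharges: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or nested stays into single episodes.

    Episodes are merged when an admission date falls on or before the
    running maximum discharge date of the preceding stays; the merged
    episode keeps the earliest admission, latest discharge, the first
    stay's category and most-responsible code, and any death flag.
    """
    if discharges.empty:
        return discharges.assign(
            admit_date=pd.to_datetime(pd.Series(dtype=object)),
            discharge_date=pd.to_datetime(pd.Series(dtype=object)),
        )
    ep = discharges.copy()
    ep["admit_date"] = pd.to_datetime(ep["admit_date"])
    missing = ep["discharge_date"].isna() | (ep["discharge_date"].astype(str) == "")
    if missing.any():
        logger.warning("skipped %d episodes with missing discharge dates", int(missing.sum()))
        ep = ep[~missing]
    ep["discharge_date"] = pd.to_datetime(ep["discharge_date"])
    ep = ep.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)
    running_max = ep.groupby("patient_id")["discharge_date"].cummax()
    prev_max = running_max.groupby(ep["patient_id"]).shift()
    new_episode = ep["admit_date"] > prev_max
    new_episode |= prev_max.isna()
    n_merged = int((~new_episode).sum())
    if n_merged:
        logger.warning("merged %d overlapping hospital stays", n_merged)
    ep["episode_id"] = new_episode.cumsum()
    agg = {
        "patient_id": ("patient_id", "first"),
        "admit_date": ("admit_date", "min"),
        "discharge_date": ("discharge_date", "max"),
        "admission_category": ("admission_category", "first"),
        "mrd_code": ("mrd_code", "first"),
        "died_in_hospital": ("died_in_hospital", "any"),
    }
    return ep.groupby("episode_id").agg(**agg).reset_index(drop=True)


def _windowed_episodes(discharges: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    eligible = _eligible(cohort)
    ep = merge_episodes(discharges)
    if ep.empty:
        return ep.assign(patient_id=pd.Series(dtype=object))
    ep = ep.merge(eligible, on="patient_id")
    ep = ep[(ep["admit_date"] >= ep["index_date"]) & (ep["admit_date"] < ep["followup_end"])]
    return ep.sort_values(["patient_id", "admit_date"], kind="mergesort").reset_index(drop=True)


def count_admissions(
    discharges: pd.DataFrame,
    cohort: pd.DataFrame,
    copd_code_sets: CaseDefinition | None = None,
    unplanned_only: bool = False,
) -> pd.DataFrame:
    """All-cause and COPD-related admission counts per eligible patient."""
    case_def = copd_code_sets or CaseDefinition()
    eligible = _eligible(cohort)
    ep = _windowed_episodes(discharges, cohort)
    if unplanned_only and len(ep):
        ep = ep[~ep["admission_category"].isin(NON_UNPLANNED_CATEGORIES)]
    if len(ep):
        ep["copd"] = case_def.matches(ep["mrd_code"])
        counts = ep.groupby("patient_id").agg(
            n_admissions_all=("admit_date", "size"), n_admissions_copd=("copd", "sum")
        )
    else:
        counts = pd.DataFrame(columns=["n_admissions_all", "n_admissions_copd"])
    out = counts.reindex(eligible["patient_id"], fill_value=0).astype(int).reset_index()
    out["any_admission"] = out["n_admissions_all"] >= 1
    return out


def flag_30day_readmissions(
    discharges: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """30-day readmission flag and count per eligible patient.

    Each non-elective, non-transfer episode whose admission falls within
    30 days (inclusive) after the immediately preceding episode's
    discharge counts as one readmission.
    """
    eligible = _eligible(cohort)
    ep = _windowed_episodes(discharges, cohort)
    if len(ep):
        prev_discharge = ep.groupby("patient_id")["discharge_date"].shift()
        gap = (ep["admit_date"] - prev_discharge).dt.days
        qualifies = (
            prev_discharge.notna()
            & ~ep["admission_category"].isin(NON_UNPLANNED_CATEGORIES)
            & (gap > 0)
            & (gap <= READMISSION_WINDOW_DAYS)
        )
        counts = qualifies.groupby(ep["patient_id"]).sum().rename("n_readmissions_30d")
    else:
        counts = pd.Series(dtype=float, name="n_readmissions_30d")
    out = counts.reindex(eligible["patient_id"], fill_value=0).astype(int).reset_index()
    out["any_readmission_30d"] = out["n_readmissions_30d"] >= 1
    return out


def classify_ed_visits(
    ed_visits: pd.DataFrame,
    discharges: pd.DataFrame,
    cohort: pd.DataFrame,
    copd_code_sets: CaseDefinition | None = None,
) -> pd.DataFrame:
    """ED visit counts per class for every eligible patient.

    ``n_ed_with_admission`` counts unscheduled ED visits that led to a
    hospital admission; ``n_ed_without_admission`` the rest. Scheduled
    ED-to-admission encounters are planned care and excluded entirely.
    An admitted ED visit with no matching discharge abstract is a
    linkage defect: logged and classified as without admission.
    """
    case_def = copd_code_sets or CaseDefinition()
    eligible = _eligible(cohort)
    cols = ["n_ed_all", "n_ed_copd", "n_ed_with_admission", "n_ed_without_admission"]
    if ed_visits.empty:
        out = pd.DataFrame(0, index=eligible["patient_id"], columns=cols)
        return out.reset_index()
    ed = ed_visits.copy()
    ed["visit_date"] = pd.to_datetime(ed["visit_date"])
    ed = ed.merge(eligible, on="patient_id")
    ed = ed[(ed["visit_date"] >= ed["index_date"]) & (ed["visit_date"] < ed["followup_end"])]

    ep = merge_episodes(discharges)
    if len(ep):
        admit_keys = set(zip(ep["patient_id"], ep["admit_date"]))
    else:
        admit_keys = set()
    keys = list(zip(ed["patient_id"], ed["visit_date"]))
    has_discharge = np.array([k in admit_keys for k in keys], dtype=bool)
    admitted = ed["admitted"].astype(bool).to_numpy()
    scheduled = ed["scheduled"].astype(bool).to_numpy()
    broken = admitted & ~has_discharge
    if broken.any():
        logger.warning(
            "%d admitted ED visits had no matching discharge; classified as without admission",
            int(broken.sum()),
        )
    admitted = admitted & has_discharge
    planned = admitted & scheduled
    ed = ed[~planned].copy()
    ed["with_admission"] = admitted[~planned]
    ed["copd"] = case_def.matches(ed["diagnosis_code"])
    counts = ed.groupby("patient_id").agg(
        n_ed_all=("visit_date", "size"),
        n_ed_copd=("copd", "sum"),
        n_ed_with_admission=("with_admission", "sum"),
    )
    counts["n_ed_without_admission"] = counts["n_ed_all"] - counts["n_ed_with_admission"]
    out = counts.reindex(eligible["patient_id"], fill_value=0).astype(int).reset_index()
    return out[["patient_id"] + cols]


def in_hospital_death(discharges: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Discharge-due-to-death flag per eligible patient (in-window stays)."""
    eligible = _eligible(cohort)
    ep = _windowed_episodes(discharges, cohort)
    if len(ep):
        died = ep.groupby("patient_id")["died_in_hospital"].any()
    else:
        died = pd.Series(dtype=bool, name="died_in_hospital")
    out = died.reindex(eligible["patient_id"], fill_value=False).astype(bool)
    return out.rename("died_in_hospital").reset_index()


def summarize_utilization(
    discharges: pd.DataFrame,
    ed_visits: pd.DataFrame,
    cohort: pd.DataFrame,
    copd_code_sets: CaseDefinition | None = None,
    unplanned_only: bool = False,
) -> pd.DataFrame:
    """One UtilizationSummary row per eligible cohort member."""
    out = count_admissions(discharges, cohort, copd_code_sets, unplanned_only)
    out = out.merge(flag_30day_readmissions(discharges, cohort), on="patient_id")
    out = out.merge(
        classify_ed_visits(ed_visits, discharges, cohort, copd_code_sets), on="patient_id"
    )
    out = out.merge(in_hospital_death(discharges, cohort), on="patient_id")
    return out
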