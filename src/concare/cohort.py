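"""COPD cohort derivation from linked claims tables.

Applies a validated administrative case definition (one or more
physician billing claims and/or hospital discharges carrying a
qualifying diagnosis code) over a recruitment window, then the
eligibility rules of a population-based incident cohort: valid patient
identifier, provincial residency, insurance coverage at index, no
qualifying event before the window (incident cases only) and age >= 35
at index. Eligible patients are followed for up to five years, censored
at death, loss of coverage (move-out) or the administrative study end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DataIntegrityError

logger = logging.getLogger(__name__)

#: Registry identifier format: one uppercase letter then seven digits.
IKN_PATTERN = re.compile(r"^[A-Z]\d{7}$")

DEFAULT_RECRUITMENT_WINDOW = ("2005-04-01", "2013-03-31")
DEFAULT_STUDY_END = "2018-03-31"

#: Exclusion precedence (first matching reason is recorded).
EXCLUSION_ORDER = ("invalid_id", "non_resident", "no_coverage", "prior_copd", "under_35")


@dataclass(frozen=True)
class CaseDefinition:
    """Diagnosis-code sets identifying a qualifying COPD event.

    Matching is prefix-based (``J44`` matches ``J44.1``) because
    administrative codes carry sub-digits. The default ICD-9 triad is
    {491, 492, 496} — chronic bronchitis, emphysema and unspecified
    chronic airway obstruction — with ICD-10 {J41–J44}.
    """

    icd9_codes: frozenset = frozenset({"491", "492", "496"})
    icd10_codes: frozenset = frozenset({"J41", "J42", "J43", "J44"})
    min_claims: int = 1
    min_discharges: int = 1
    combination: str = "any-of"

    def __post_init__(self):
        if not (self.icd9_codes or self.icd10_codes):
            raise ValueError("at least one diagnosis-code set must be non-empty")

    @property
    def all_codes(self) -> tuple:
        return tuple(sorted(self.icd9_codes | self.icd10_codes))

    def matches(self, codes: pd.Series) -> pd.Series:
        """Vectorized prefix match of a code column against the sets."""
        codes = codes.astype(str)
        result = pd.Series(False, index=codes.index)
        for prefix in self.all_codes:
            result |= codes.str.startswith(prefix)
        return result

    @classmethod
    def from_yaml(cls, path) -> "CaseDefinition":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(
            icd9_codes=frozenset(str(c) for c in raw.get("icd9_codes", [])),
            icd10_codes=frozenset(str(c) for c in raw.get("icd10_codes", [])),
            min_claims=int(raw.get("min_claims", 1)),
            min_discharges=int(raw.get("min_discharges", 1)),
        )


def _qualifying_events(
    claims: pd.DataFrame, discharges: pd.DataFrame, case_def: CaseDefinition
) -> pd.DataFrame:
    """All qualifying events as (patient_id, event_date)."""
    frames = []
    if len(claims):
        codes = claims["diagnosis_code"]
        malformed = codes.isna() | (codes.astype(str).str.strip() == "")
        if malformed.any():
            logger.warning("ignored %d claims with malformed diagnosis codes", int(malformed.sum()))
        sub = claims[~malformed]
        hit = case_def.matches(sub["diagnosis_code"])
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": sub.loc[hit, "patient_id"],
                    "event_date": pd.to_datetime(sub.loc[hit, "service_date"]),
                }
            )
        )
    if len(discharges):
        hit = case_def.matches(discharges["mrd_code"])
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": discharges.loc[hit, "patient_id"],
                    "event_date": pd.to_datetime(discharges.loc[hit, "admit_date"]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "event_date"])
    return pd.concat(frames, ignore_index=True)


def find_index_date(
    claims: pd.DataFrame,
    discharges: pd.DataFrame,
    case_def: CaseDefinition | None = None,
    recruitment_window: tuple[str, str] = DEFAULT_RECRUITMENT_WINDOW,
) -> pd.DataFrame:
    """Earliest qualifying event per patient inside the recruitment window.

    Returns one row per patient with any qualifying event: columns
    ``patient_id``, ``first_event`` (earliest qualifying event anywhere),
    ``index_date`` (earliest inside the window; NaT when the patient has
    a pre-window history and is therefore not an incident case) and
    ``prior_copd``.
    """
    case_def = case_def or CaseDefinition()
    start, end = (pd.Timestamp(d) for d in recruitment_window)
    if not start < end:
        raise ValueError("recruitment window is not well ordered")
    events = _qualifying_events(claims, discharges, case_def)
    if events.empty:
        return pd.DataFrame(columns=["patient_id", "first_event", "index_date", "prior_copd"])
    first = events.groupby("patient_id")["event_date"].min().rename("first_event")
    in_window = events[(events["event_date"] >= start) & (events["event_date"] <= end)]
    index = in_window.groupby("patient_id")["event_date"].min().rename("index_date")
    out = first.to_frame().join(index).reset_index()
    out["prior_copd"] = out["first_event"] < start
    out.loc[out["prior_copd"], "index_date"] = pd.NaT
    # patients whose only qualifying events postdate the window are not
    # candidates (neither incident in-window nor prevalent before it)
    return out[out["index_date"].notna() | out["prior_copd"]].reset_index(drop=True)


def apply_exclusions(
    persons: pd.DataFrame, index_dates: pd.DataFrame, min_age: float = 35.0
) -> pd.DataFrame:
    """Partition patients with a qualifying event into eligible vs excluded.

    Exclusions are applied in the documented precedence order
    (:data:`EXCLUSION_ORDER`); each excluded patient carries exactly the
    first matching reason. ``no_coverage`` means the insurance interval
    does not contain the index date.
    """
    cohort = index_dates.merge(persons, on="patient_id", how="left")
    birth = pd.to_datetime(cohort["birth_date"])
    cov_start = pd.to_datetime(cohort["coverage_start"])
    cov_end = pd.to_datetime(cohort["coverage_end"])
    idx = pd.to_datetime(cohort["index_date"])
    age = (idx - birth).dt.days / 365.25

    reason = pd.Series("", index=cohort.index, dtype=object)
    checks = [
        ("invalid_id", ~cohort["patient_id"].astype(str).str.match(IKN_PATTERN)),
        ("non_resident", ~cohort["ontario_resident"].astype(bool)),
        ("no_coverage", (cov_start > idx) | (cov_end <= idx)),
        ("prior_copd", cohort["prior_copd"].astype(bool)),
        ("under_35", age < min_age),
    ]
    for name, mask in checks:
        mask = mask.fillna(False) if mask.dtype == object else mask
        reason = reason.mask((reason == "") & mask.fillna(False), name)
    # a patient whose only index is absent for a non-prior reason cannot occur:
    # index is NaT only when prior_copd is set.
    out = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "index_date": idx,
            "age_at_index": age,
            "eligible": reason == "",
            "exclusion_reason": reason,
        }
    )
    out.loc[out["eligible"], "exclusion_reason"] = ""
    return out


def define_followup(
    cohort: pd.DataFrame,
    persons: pd.DataFrame,
    horizon_years: float = 5.0,
    study_end: str = DEFAULT_STUDY_END,
) -> pd.DataFrame:
    """Attach follow-up interval and censoring reason to eligible rows.

    ``followup_end = min(index + horizon, death, coverage_end,
    study_end)``; ties resolve in that priority order. Idempotent: the
    result is derived only from index dates and the person registry, so
    re-application reproduces itself.
    """
    merged = cohort.merge(
        persons[["patient_id", "death_date", "coverage_end"]], on="patient_id", how="left"
    )
    idx = pd.to_datetime(merged["index_date"])
    death = pd.to_datetime(merged["death_date"])
    cov_end = pd.to_datetime(merged["coverage_end"])
    eligible = merged["eligible"].astype(bool)
    if ((death < idx) & eligible).any():
        bad = merged.loc[(death < idx) & eligible, "patient_id"].iloc[0]
        raise DataIntegrityError(f"death before index date for patient {bad}")

    horizon_end = idx + pd.to_timedelta(np.round(horizon_years * 365.25), unit="D")
    end_admin = pd.Timestamp(study_end)
    candidates = pd.concat(
        [horizon_end, death, cov_end, pd.Series(end_admin, index=merged.index)], axis=1
    )
    fu_end = candidates.min(axis=1)
    reason = np.select(
        [fu_end == horizon_end, fu_end == death, fu_end == cov_end],
        ["end_of_window", "death", "moved"],
        default="end_of_window",
    )
    out = cohort.copy()
    out["followup_start"] = idx
    out["followup_end"] = fu_end.where(eligible, pd.NaT)
    out["censor_reason"] = np.where(eligible, reason, "none")
    out.loc[~eligible, "followup_start"] = pd.NaT
    return out


def build_cohort(
    tables: dict,
    case_def: CaseDefinition | None = None,
    recruitment_window: tuple[str, str] = DEFAULT_RECRUITMENT_WINDOW,
    min_age: float = 35.0,
    horizon_years: float = 5.0,
    study_end: str = DEFAULT_STUDY_END,
) -> pd.DataFrame:
    """End-to-end cohort derivation from a dict of linked tables."""
    index_dates = find_index_date(
        tables["claims"], tables["discharges"], case_def, recruitment_window
    )
    cohort = apply_exclusions(tables["persons"], index_dates, min_age=min_age)
    return define_followup(
        cohort, tables["persons"], horizon_years=horizon_years, study_end=study_end
    )
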