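"""Continuity-of-care indices over a patient's outpatient physician network.

Three claims-based indices are computed from the ordered sequence of a
patient's outpatient physician visits over follow-up. With ``N`` total
visits distributed as counts ``n_j`` over ``k`` distinct physicians:

* **UPC** (usual provider of care): ``max_j n_j / N`` — the share of
  visits made to the most-visited provider. 1 when a single provider
  delivers all care.
* **COC** (Bice–Boxerman concentration of care):
  ``(sum_j n_j^2 - N) / (N (N - 1))`` — the probability that two
  distinct visits drawn without replacement share a provider. 0 when
  every visit is to a different provider, 1 when all visits are to the
  same provider. Requires ``N >= 2``.
* **SECON** (sequential continuity): the fraction of adjacent visit
  pairs made to the same provider. 0 for strict alternation between two
  providers, 1 for an unbroken run. Order-dependent; requires ``N >= 2``.

``COC <= UPC`` always, with equality exactly when ``k = 1``.

Visit sequences are built from billing claims restricted to outpatient
care by the family-physician (FP) and respirology-group (RESP)
specialties, within the half-open follow-up interval
``[index_date, followup_end)``. Multiple same-day claims to the same
physician collapse to a single visit; same-day claims to different
physicians remain distinct visits ordered date-then-physician-id.
Patients with five or fewer visits are flagged ``not_assessed`` and
excluded from index-based analyses.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: Specialty groups whose claims enter the continuity indices.
INDEX_SPECIALTIES = ("FP", "RESP")
#: Visit-count threshold below which indices are not assessed.
MIN_VISITS = 5


@dataclass
class VisitSequence:
    """Ordered provider-labelled outpatient visits for one patient.

    ``visits`` is a list of ``(service_date, physician_id,
    specialty_group)`` tuples sorted by date then physician id.
    """

    patient_id: str
    visits: list = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.visits)

    @property
    def provider_counts(self) -> Counter:
        return Counter(v[1] for v in self.visits)

    @property
    def k(self) -> int:
        return len(self.provider_counts)

    @property
    def providers(self) -> list:
        """Provider label of each visit, in order."""
        return [v[1] for v in self.visits]


def _counts(seq) -> list[int]:
    if isinstance(seq, VisitSequence):
        return list(seq.provider_counts.values())
    return list(Counter(seq).values())


def _providers(seq) -> list:
    if isinstance(seq, VisitSequence):
        return seq.providers
    return list(seq)


def upc(seq) -> float:
    """Usual-provider-of-care index: max_j n_j / N.

    Accepts a :class:`VisitSequence` or any ordered iterable of provider
    labels. Requires at least one visit.
    """
    counts = _counts(seq)
    total = sum(counts)
    if total < 1:
        raise UndefinedIndexError("UPC is undefined for an empty visit sequence")
    return max(counts) / total


def coc(seq) -> float:
    """Bice–Boxerman concentration-of-care index.

    ``(sum_j n_j^2 - N) / (N (N - 1))``: the probability that two
    distinct visits drawn without replacement were made to the same
    provider. Requires ``N >= 2``.
    """
    counts = _counts(seq)
    total = sum(counts)
    if total < 2:
        raise UndefinedIndexError("COC is undefined for fewer than 2 visits")
    return (sum(c * c for c in counts) - total) / (total * (total - 1))


def secon(seq) -> float:
    """Sequential-continuity index: fraction of adjacent same-provider pairs.

    Requires ``N >= 2``; depends on visit order, unlike UPC and COC.
    """
    providers = _providers(seq)
    total = len(providers)
    if total < 2:
        raise UndefinedIndexError("SECON is undefined for fewer than 2 visits")
    matches = sum(a == b for a, b in zip(providers, providers[1:]))
    return matches / (total - 1)


def classify_predominant_provider(seq: VisitSequence) -> tuple[str, float]:
    """FP-vs-specialist predominance and the FP visit share.

    The group receiving strictly more visits wins; an exact tie is
    assigned to FP, the system's default attachment point.
    """
    if seq.N < 1:
        raise UndefinedIndexError("predominance is undefined with no visits")
    fp = sum(1 for v in seq.visits if v[2] == "FP")
    share = fp / seq.N
    return ("FP" if share >= 0.5 else "SP"), share


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371 km). Vectorized.

    Raises ``ValueError`` naming the offending coordinate field when a
    latitude falls outside [-90, 90] or a longitude outside [-180, 180].
    """
    arrays = {
        "latitude_1": np.asarray(lat1, dtype=float),
        "longitude_1": np.asarray(lon1, dtype=float),
        "latitude_2": np.asarray(lat2, dtype=float),
        "longitude_2": np.asarray(lon2, dtype=float),
    }
    for name, arr in arrays.items():
        bound = 90.0 if name.startswith("lat") else 180.0
        finite = arr[np.isfinite(arr)]
        if finite.size and (np.abs(finite) > bound).any():
            raise ValueError(f"{name} outside [-{bound:g}, {bound:g}]")
    la1, lo1, la2, lo2 = (np.radians(arrays[k]) for k in arrays)
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if np.isscalar(lat1) and np.isscalar(lat2) else d


# ---------------------------------------------------------------------------
# claims -> sequences / profiles
# ---------------------------------------------------------------------------

def _eligible_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort[cohort["eligible"].astype(bool)].copy()
    out["index_date"] = pd.to_datetime(out["index_date"])
    out["followup_end"] = pd.to_datetime(out["followup_end"])
    return out


def _window_claims(claims: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Outpatient FP/RESP claims inside each patient's follow-up window,
    collapsed to one visit per (patient, date, physician)."""
    eligible = _eligible_cohort(cohort)
    sub = claims[
        (claims["setting"] == "outpatient")
        & claims["specialty"].isin(INDEX_SPECIALTIES)
    ].copy()
    orphans = ~sub["patient_id"].isin(set(eligible["patient_id"]))
    if orphans.any():
        logger.info("ignored %d claims for patients outside the cohort", int(orphans.sum()))
    sub = sub[~orphans]
    sub["service_date"] = pd.to_datetime(sub["service_date"])
    sub = sub.merge(
        eligible[["patient_id", "index_date", "followup_end"]], on="patient_id"
    )
    sub = sub[
        (sub["service_date"] >= sub["index_date"])
        & (sub["service_date"] < sub["followup_end"])
    ]
    sub = sub.drop_duplicates(["patient_id", "service_date", "physician_id"])
    return sub.sort_values(
        ["patient_id", "service_date", "physician_id"], kind="mergesort"
    ).reset_index(drop=True)


def build_visit_sequences(claims: pd.DataFrame, cohort: pd.DataFrame) -> dict[str, VisitSequence]:
    """Per-patient ordered visit sequences for every eligible cohort member.

    Patients with no in-window claims receive an empty sequence.
    """
    windowed = _window_claims(claims, cohort)
    sequences = {
        pid: VisitSequence(pid) for pid in _eligible_cohort(cohort)["patient_id"]
    }
    for pid, grp in windowed.groupby("patient_id", sort=False):
        sequences[pid].visits = list(
            zip(
                grp["service_date"].dt.strftime("%Y-%m-%d"),
                grp["physician_id"],
                grp["specialty"],
            )
        )
    return sequences


def compute_profiles(
    claims: pd.DataFrame,
    cohort: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    providers: pd.DataFrame | None = None,
    min_visits: int = MIN_VISITS,
) -> pd.DataFrame:
    """Continuity profile for every eligible cohort member (vectorized).

    Columns: patient_id, n_visits, upc, coc, secon, predominant_group,
    fp_visit_share, distance_km, coci_category. Indices are NaN where
    undefined; ``coci_category`` is filled by :func:`dichotomize_coci`.
    Distance to the usual provider is computed when ``persons`` (with
    latitude/longitude) and ``providers`` (with office coordinates) are
    supplied, using max-visit-count provider, ties broken by earliest
    first visit then physician id.
    """
    windowed = _window_claims(claims, cohort)
    eligible = _eligible_cohort(cohort)

    pc = (
        windowed.groupby(["patient_id", "physician_id"])
        .agg(n=("service_date", "size"), first_visit=("service_date", "min"))
        .reset_index()
    )
    pc["n2"] = pc["n"] ** 2
    agg = pc.groupby("patient_id").agg(
        n_visits=("n", "sum"), k=("n", "size"), sumsq=("n2", "sum"), nmax=("n", "max")
    )
    same = (windowed["patient_id"] == windowed["patient_id"].shift()) & (
        windowed["physician_id"] == windowed["physician_id"].shift()
    )
    agg["matches"] = same.groupby(windowed["patient_id"]).sum()
    fp = windowed["specialty"] == "FP"
    agg["fp_n"] = fp.groupby(windowed["patient_id"]).sum()

    profiles = agg.reindex(eligible["patient_id"]).fillna(0).reset_index()
    N = profiles["n_visits"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        profiles["upc"] = np.where(N >= 1, profiles["nmax"] / N, np.nan)
        profiles["coc"] = np.where(
            N >= 2, (profiles["sumsq"] - N) / (N * (N - 1)), np.nan
        )
        profiles["secon"] = np.where(N >= 2, profiles["matches"] / (N - 1), np.nan)
        fp_share = np.where(N >= 1, profiles["fp_n"] / N, np.nan)
    profiles["fp_visit_share"] = fp_share
    profiles["predominant_group"] = np.where(
        N < 1, "", np.where(fp_share >= 0.5, "FP", "SP")
    )
    profiles["n_visits"] = profiles["n_visits"].astype(int)

    profiles["distance_km"] = _usual_provider_distance(pc, profiles, persons, providers)
    profiles = profiles[
        [
            "patient_id",
            "n_visits",
            "upc",
            "coc",
            "secon",
            "predominant_group",
            "fp_visit_share",
            "distance_km",
        ]
    ]
    return dichotomize_coci(profiles, min_visits=min_visits)


def _usual_provider_distance(pc, profiles, persons, providers):
    if persons is None or providers is None:
        return np.nan
    usual = pc.sort_values(
        ["patient_id", "n", "first_visit", "physician_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("patient_id")
    merged = (
        profiles[["patient_id"]]
        .merge(usual[["patient_id", "physician_id"]], on="patient_id", how="left")
        .merge(
            persons[["patient_id", "latitude", "longitude"]], on="patient_id", how="left"
        )
        .merge(
            providers[["physician_id", "office_latitude", "office_longitude"]],
            on="physician_id",
            how="left",
        )
    )
    dist = np.full(len(merged), np.nan)
    ok = merged[["latitude", "longitude", "office_latitude", "office_longitude"]].notna().all(axis=1)
    if ok.any():
        dist[ok.to_numpy()] = haversine_km(
            merged.loc[ok, "latitude"].to_numpy(),
            merged.loc[ok, "longitude"].to_numpy(),
            merged.loc[ok, "office_latitude"].to_numpy(),
            merged.loc[ok, "office_longitude"].to_numpy(),
        )
    return dist


def dichotomize_coci(
    profiles: pd.DataFrame, min_visits: int = MIN_VISITS
) -> pd.DataFrame:
    """Assign the median-cut COCI category.

    The median is computed over assessable patients only (more than
    ``min_visits`` visits); scores at or below the median are ``low``
    (the convention that makes the low group the weakly larger one),
    above it ``high``. Patients with ``N <= min_visits`` are
    ``not_assessed``.
    """
    out = profiles.copy()
    assessable = out["n_visits"] > min_visits
    if not assessable.any():
        raise ValueError("no patients with enough visits to assess continuity")
    median = float(out.loc[assessable, "coc"].median())
    category = np.where(out["coc"] <= median, "low", "high")
    out["coci_category"] = np.where(assessable, category, "not_assessed")
    out.attrs["coc_median"] = median
    return out
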