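"""Synthetic linked administrative-claims generator.

Emits the five linked tables a provincial single-payer claims analysis
consumes — person registry, physician billing claims, hospital
discharge abstracts, emergency-department records and a physician
registry — plus a ground-truth table holding each patient's true
continuity indices and planted outcome probability.

Design of the generative model (see docs/methods.md for the full
account):

* Each patient receives a first-diagnosis date uniform over the
  recruitment window; the first billing claim falls on that date and
  carries a qualifying diagnosis code.
* The 5-year outpatient visit count is 1 + negative binomial
  (heavy right tail); visit dates are uniform over follow-up, sorted.
* Visits are allocated over a personal provider pool via a symmetric
  Dirichlet-multinomial: weights ~ Dirichlet(alpha, ..., alpha), visit
  providers i.i.d. categorical given the weights. Small alpha
  concentrates care (COC -> 1), large alpha disperses it.
* Unplanned utilization follows a logistic model on standardized
  covariates plus the *true* low-continuity indicator (dichotomized at
  the realized-cohort median), so the downstream pipeline can be
  checked against a planted odds ratio.

Determinism: a fixed root seed spawns independent numpy substreams per
table, so identical configs reproduce every table byte-for-byte.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig

EPOCH = np.datetime64("1970-01-01")

COPD_ICD9 = ("491", "492", "496")
COPD_ICD10 = ("J41", "J42", "J43", "J44")
COPD_CODES = COPD_ICD9 + COPD_ICD10
#: Non-qualifying codes seen in respiratory/primary-care billing.
OTHER_CODES = ("J18", "I10", "E11", "I50", "M54", "Z00")

# Standardization constants for the outcome linear predictor.
AGE_CENTER, AGE_SCALE = 61.5, 14.6
ADG_CENTER, ADG_SCALE = 6.5, 3.0
MARG_CENTER = 3.0


def _day(iso: str) -> int:
    """ISO date -> integer day offset from the Unix epoch."""
    return int((np.datetime64(iso) - EPOCH) / np.timedelta64(1, "D"))


def _iso(days: np.ndarray) -> np.ndarray:
    """Integer day offsets -> ISO-8601 strings; NaN -> empty string."""
    days = np.asarray(days, dtype=float)
    out = np.full(days.shape, "", dtype=object)
    ok = np.isfinite(days)
    if ok.any():
        stamps = (EPOCH + days[ok].astype(int)).astype("datetime64[D]")
        out[ok] = stamps.astype(str)
    return out


def linear_predictor(
    *,
    age: float | np.ndarray,
    sex_m: float | np.ndarray,
    adg: float | np.ndarray,
    rural: float | np.ndarray,
    marginalization: float | np.ndarray,
    low_coci: float | np.ndarray,
    coefficients: Mapping[str, float],
) -> np.ndarray:
    """Planted log-odds of unplanned admission for given covariates."""
    b = coefficients
    return (
        b.get("intercept", 0.0)
        + b.get("low_coci", 0.0) * np.asarray(low_coci, dtype=float)
        + b.get("age", 0.0) * (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE
        + b.get("sex_m", 0.0) * np.asarray(sex_m, dtype=float)
        + b.get("adg", 0.0) * (np.asarray(adg, dtype=float) - ADG_CENTER) / ADG_SCALE
        + b.get("rural", 0.0) * np.asarray(rural, dtype=float)
        + b.get("marginalization", 0.0)
        * (np.asarray(marginalization, dtype=float) - MARG_CENTER)
    )


# ---------------------------------------------------------------------------
# visit allocation
# ---------------------------------------------------------------------------

def allocate_visits(
    total_visits: int,
    pool: Sequence,
    dispersion_alpha: float,
    rng: np.random.Generator,
) -> list:
    """Draw an ordered provider sequence for one patient.

    Weights over the pool are symmetric Dirichlet(alpha); visit
    providers are i.i.d. categorical given the weights (the marginal
    counts are Dirichlet-multinomial). ``alpha <= ~0`` degenerates to a
    single randomly chosen provider; large ``alpha`` approaches a
    uniform spread, driving the expected concentration of care
    (1 + alpha) / (1 + k * alpha) down toward 1/k.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("provider pool is empty")
    if total_visits < 1:
        raise ValueError("total_visits must be >= 1")
    k = len(pool)
    if dispersion_alpha <= 1e-9:
        weights = np.zeros(k)
        weights[rng.integers(0, k)] = 1.0
    else:
        weights = rng.dirichlet(np.full(k, float(dispersion_alpha)))
    idx = rng.choice(k, size=total_visits, p=weights)
    return [pool[i] for i in idx]


# ---------------------------------------------------------------------------
# per-patient outcome simulation (reference implementation)
# ---------------------------------------------------------------------------

def simulate_outcomes(
    person: Mapping,
    continuity_truth: Mapping,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict:
    """Simulate one patient's discharge episodes, ED visits and death flag.

    ``person`` must provide ``age``, ``sex`` ('F'/'M'), ``adg_score``,
    ``rural``, ``marginalization_composite``, ``index_day`` and
    ``followup_end_day`` (integer day offsets) and optionally
    ``death_day`` (NaN/None when the registry records no death).
    ``continuity_truth`` must provide ``true_low_coci``.

    Returns a dict with ``episodes`` (list of dicts), ``ed_visits``
    (list of dicts), ``death_day`` (possibly adjusted onto an in-hospital
    discharge) and ``any_admission``.
    """
    config.validate()
    lp = float(
        linear_predictor(
            age=person["age"],
            sex_m=1.0 if person["sex"] == "M" else 0.0,
            adg=person["adg_score"],
            rural=1.0 if person["rural"] else 0.0,
            marginalization=person["marginalization_composite"],
            low_coci=1.0 if continuity_truth["true_low_coci"] else 0.0,
            coefficients=config.outcome_coefficients,
        )
    )
    index_day = int(person["index_day"])
    fu_end = int(person["followup_end_day"])
    death_day = person.get("death_day")
    if death_day is None or (isinstance(death_day, float) and np.isnan(death_day)):
        death_day = None
    else:
        death_day = int(death_day)

    any_adm = rng.random() < expit(lp)
    episodes: list[dict] = []
    if any_adm and fu_end > index_day:
        n_ep = 1 + rng.poisson(config.extra_admission_mean)
        p_re = expit(lp + config.readmission_intercept_shift)
        admit = index_day + int(rng.random() * (fu_end - index_day))
        prev_dis = None
        for _ in range(n_ep):
            if prev_dis is not None:
                if rng.random() < p_re:
                    admit, category = prev_dis + int(rng.integers(1, 31)), "emergent"
                else:
                    admit = prev_dis + int(rng.integers(31, 330))
                    category = _draw_category(rng.random())
            else:
                category = _draw_category(rng.random())
            if admit >= fu_end:
                break
            discharge = admit + 2 + int(rng.poisson(4.0))
            mrd = (
                COPD_CODES[rng.integers(0, len(COPD_CODES))]
                if rng.random() < 0.30
                else OTHER_CODES[rng.integers(0, len(OTHER_CODES))]
            )
            episodes.append(
                {
                    "admit_day": admit,
                    "discharge_day": discharge,
                    "admission_category": category,
                    "mrd_code": mrd,
                    "secondary_code": OTHER_CODES[rng.integers(0, len(OTHER_CODES))],
                    "died_in_hospital": False,
                }
            )
            prev_dis = discharge

    horizon = int(round(config.followup_years * 365.25))
    death_day, episodes = _reconcile_death(
        death_day, episodes, index_day, horizon, rng.random()
    )

    ed_visits: list[dict] = []
    for ep in episodes:
        if ep["admission_category"] == "emergent" and rng.random() < 0.85:
            ed_visits.append(
                {
                    "visit_day": ep["admit_day"],
                    "diagnosis_code": ep["mrd_code"],
                    "admitted": True,
                    "scheduled": rng.random() < 0.02,
                }
            )
    if rng.random() < expit(lp + config.ed_intercept_shift) and fu_end > index_day:
        for _ in range(1 + rng.poisson(1.8)):
            ed_visits.append(
                {
                    "visit_day": index_day + int(rng.random() * (fu_end - index_day)),
                    "diagnosis_code": (
                        COPD_CODES[rng.integers(0, len(COPD_CODES))]
                        if rng.random() < 0.30
                        else OTHER_CODES[rng.integers(0, len(OTHER_CODES))]
                    ),
                    "admitted": False,
                    "scheduled": rng.random() < 0.01,
                }
            )
    return {
        "episodes": episodes,
        "ed_visits": ed_visits,
        "death_day": death_day,
        "any_admission": bool(episodes),
    }


def _draw_category(u: float) -> str:
    if u < 0.10:
        return "elective"
    if u < 0.15:
        return "transfer"
    return "emergent"


def _reconcile_death(death_day, episodes, index_day, horizon, u_hospital):
    """Make the registry death date consistent with discharge episodes.

    Deaths falling inside a stay become in-hospital deaths (the stay is
    truncated at the death date); otherwise a death during follow-up is
    relocated onto the final discharge with probability ~0.55 so that
    discharge-due-to-death is a non-degenerate outcome, mirroring the
    high in-hospital mortality seen in newly diagnosed COPD cohorts.
    """
    if death_day is None:
        return None, episodes
    if episodes and death_day <= index_day + horizon and u_hospital < 0.55:
        last = episodes[-1]
        last["discharge_day"] = min(last["discharge_day"], max(death_day, last["admit_day"] + 1))
        last["died_in_hospital"] = True
        return last["discharge_day"], episodes
    kept = []
    for ep in episodes:
        if ep["admit_day"] > death_day:
            continue
        if ep["discharge_day"] > death_day:
            ep["discharge_day"] = max(death_day, ep["admit_day"] + 1)
            ep["died_in_hospital"] = True
        kept.append(ep)
    return death_day, kept


# ---------------------------------------------------------------------------
# full dataset generation (vectorized)
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate the linked synthetic tables.

    Returns a dict with keys ``persons``, ``claims``, ``discharges``,
    ``ed_visits``, ``providers`` and ``truth``. All dates are ISO-8601
    strings; every foreign key resolves; rerunning with the same config
    reproduces identical tables.
    """
    config.validate()
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    r_person, r_prov, r_visit, r_out, r_ed = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    rec0, rec1 = _day(config.recruitment_start), _day(config.recruitment_end)
    study_end = _day(config.study_end)
    horizon = int(round(config.followup_years * 365.25))
    registry_end = study_end + 275  # registry horizon past administrative censoring

    # ----- persons -------------------------------------------------------
    diag = r_person.integers(rec0, rec1 + 1, n)
    age = r_person.normal(AGE_CENTER, AGE_SCALE, n)
    bad = (age < 31.0) | (age > 99.0)
    while bad.any():
        age[bad] = r_person.normal(AGE_CENTER, AGE_SCALE, int(bad.sum()))
        bad = (age < 31.0) | (age > 99.0)
    birth = diag - np.round(age * 365.25).astype(np.int64)
    sex = np.where(r_person.random(n) < 0.5, "F", "M")
    lat = np.round(r_person.uniform(42.5, 49.5, n), 4)
    lon = np.round(r_person.uniform(-83.0, -75.0, n), 4)
    quintile = r_person.integers(1, 6, n)
    marg = np.round(r_person.uniform(1.0, 5.0, (n, 4)), 2)
    marg_comp = np.round(marg.mean(axis=1), 2)
    rural = r_person.random(n) < config.p_rural
    adg = 1 + r_person.poisson(5.5, n)

    death_rate = float(config.censoring_rates["death"])
    move_rate = float(config.censoring_rates["move"])
    death = np.full(n, np.inf)
    if death_rate > 0:
        death = diag + np.ceil(r_person.exponential(365.25 / death_rate, n))
    death_day = np.where(death <= registry_end, death, np.nan)
    cov_end = np.full(n, float(registry_end))
    if move_rate > 0:
        cov_end = np.minimum(
            diag + np.ceil(r_person.exponential(365.25 / move_rate, n)),
            float(registry_end),
        )
    cov_end = cov_end.astype(np.int64)
    cov_start = np.full(n, _day("2002-01-01"), dtype=np.int64)
    late = r_person.random(n) < config.p_late_coverage
    cov_start[late] = diag[late] + 90
    resident = r_person.random(n) >= config.p_nonresident
    invalid = r_person.random(n) < config.p_invalid_id
    pid = np.array(
        [f"BAD{i:07d}" if invalid[i] else f"P{i:07d}" for i in range(n)], dtype=object
    )
    prior = r_person.random(n) < config.p_prior_copd

    fu_end = np.minimum.reduce(
        [
            diag + horizon,
            np.where(np.isnan(death_day), np.inf, death_day),
            cov_end.astype(float),
            np.full(n, float(study_end)),
        ]
    ).astype(np.int64)

    # ----- providers ------------------------------------------------------
    n_fp = max(30, n // 40)
    n_sp = max(8, n // 400)
    prov_ids = np.array(
        [f"F{i:05d}" for i in range(n_fp)] + [f"S{i:05d}" for i in range(n_sp)],
        dtype=object,
    )
    prov_spec = np.array(["FP"] * n_fp + ["RESP"] * n_sp, dtype=object)
    prov_lat = np.round(r_prov.uniform(42.5, 49.5, n_fp + n_sp), 4)
    prov_lon = np.round(r_prov.uniform(-83.0, -75.0, n_fp + n_sp), 4)

    # ----- provider pools and visit weights ------------------------------
    P = config.provider_pool_size
    sp_pred = r_visit.random(n) < config.p_specialist_predominant
    n_lead = max(1, int(round(0.7 * P)))
    fp_draw = r_visit.integers(0, n_fp, (n, P))
    sp_draw = n_fp + r_visit.integers(0, n_sp, (n, P))
    lead = np.where(sp_pred[:, None], sp_draw, fp_draw)
    tail = np.where(sp_pred[:, None], fp_draw, sp_draw)
    pool = np.empty((n, P), dtype=np.int64)
    pool[:, :n_lead] = lead[:, :n_lead]
    pool[:, n_lead:] = tail[:, n_lead:]

    # Symmetric Dirichlet weights, sorted descending so the dominant
    # weight sits on the designated predominant group's slots: the
    # sorted vector is the same exchangeable Dirichlet up to relabeling
    # (COC/UPC/SECON distributions are unaffected) but makes
    # p_specialist_predominant actually govern realized predominance.
    alpha = float(config.dispersion_alpha)
    if alpha <= 1e-9:
        weights = np.zeros((n, P))
        weights[:, 0] = 1.0
    else:
        gamma = r_visit.gamma(alpha, 1.0, (n, P))
        total = gamma.sum(axis=1)
        degenerate = total <= 0.0
        if degenerate.any():
            gamma[degenerate] = 0.0
            gamma[np.nonzero(degenerate)[0], 0] = 1.0
            total = gamma.sum(axis=1)
        weights = np.sort(gamma, axis=1)[:, ::-1] / total[:, None]

    # ----- visit sequences ------------------------------------------------
    p_nb = config.visit_dispersion / (config.visit_dispersion + config.mean_visits)
    nvis = 1 + r_visit.negative_binomial(config.visit_dispersion, p_nb, n)
    total_visits = int(nvis.sum())
    starts = np.concatenate([[0], np.cumsum(nvis)[:-1]]).astype(np.int64)
    offs = r_visit.integers(0, horizon, total_visits)
    offs[starts] = 0  # the index diagnosis visit falls on the diagnosis date
    u_prov = r_visit.random(total_visits)
    u_dx = r_visit.random(total_visits)
    copd_idx = r_visit.integers(0, len(COPD_CODES), total_visits)
    other_idx = r_visit.integers(0, len(OTHER_CODES), total_visits)
    u_setting = r_visit.random(total_visits)
    prior_rows = np.nonzero(prior)[0]
    prior_gap = r_visit.integers(30, 1001, prior_rows.size)
    prior_code = r_visit.integers(0, len(COPD_CODES), prior_rows.size)

    cum_w = np.cumsum(weights, axis=1)
    prov_local = np.empty(total_visits, dtype=np.int64)
    for i in range(n):
        s, e = starts[i], starts[i] + nvis[i]
        prov_local[s:e] = np.searchsorted(cum_w[i], u_prov[s:e], side="right")
    np.clip(prov_local, 0, P - 1, out=prov_local)

    pat_rep = np.repeat(np.arange(n), nvis)
    prov_of_visit = pool[pat_rep, prov_local]
    visit_day = diag[pat_rep] + offs
    is_first = np.zeros(total_visits, dtype=bool)
    is_first[starts] = True
    is_copd = is_first | (u_dx < 0.25)
    code = np.where(
        is_copd,
        np.take(np.array(COPD_CODES, dtype=object), copd_idx),
        np.take(np.array(OTHER_CODES, dtype=object), other_idx),
    )
    setting = np.where(~is_first & (u_setting < 0.02), "other", "outpatient")
    keep = visit_day < fu_end[pat_rep]

    # ----- ground-truth continuity over realized follow-up ----------------
    tmask = keep & (setting == "outpatient")
    tdf = pd.DataFrame(
        {"p": pat_rep[tmask], "d": visit_day[tmask], "j": prov_of_visit[tmask]}
    ).drop_duplicates()  # same-day same-physician claims are one visit
    tdf = tdf.sort_values(["p", "d", "j"], kind="mergesort").reset_index(drop=True)
    counts = tdf.groupby(["p", "j"], sort=True).size().rename("n").reset_index()
    counts["n2"] = counts["n"] ** 2
    agg = counts.groupby("p").agg(
        N=("n", "sum"), k=("n", "size"), sumsq=("n2", "sum"), nmax=("n", "max")
    )
    same = (tdf["p"] == tdf["p"].shift()) & (tdf["j"] == tdf["j"].shift())
    agg["matches"] = same.groupby(tdf["p"]).sum()
    fp_visit = prov_spec[tdf["j"].to_numpy()] == "FP"
    agg["fp_n"] = pd.Series(fp_visit, index=tdf.index).groupby(tdf["p"]).sum()
    agg = agg.reindex(np.arange(n)).fillna({"N": 0, "k": 0, "sumsq": 0, "nmax": 0, "matches": 0, "fp_n": 0})

    N = agg["N"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        upc_t = np.where(N >= 1, agg["nmax"].to_numpy(float) / N, np.nan)
        coc_t = np.where(
            N >= 2, (agg["sumsq"].to_numpy(float) - N) / (N * (N - 1)), np.nan
        )
        secon_t = np.where(N >= 2, agg["matches"].to_numpy(float) / (N - 1), np.nan)
        fp_share_t = np.where(N >= 1, agg["fp_n"].to_numpy(float) / N, np.nan)
    pred_t = np.where(fp_share_t >= 0.5, "FP", "SP")

    eligible_t = N > 5
    coc_med = float(np.median(coc_t[eligible_t])) if eligible_t.any() else np.nan
    coc_fill = np.where(np.isnan(coc_t), 1.0, coc_t)  # single-visit: fully concentrated
    low_t = coc_fill <= coc_med if np.isfinite(coc_med) else np.zeros(n, bool)

    # ----- outcomes -------------------------------------------------------
    lp = linear_predictor(
        age=age,
        sex_m=(sex == "M").astype(float),
        adg=adg,
        rural=rural.astype(float),
        marginalization=marg_comp,
        low_coci=low_t.astype(float),
        coefficients=config.outcome_coefficients,
    )
    p_adm = expit(lp)
    any_adm = r_out.random(n) < p_adm
    n_ep = np.where(any_adm, 1 + r_out.poisson(config.extra_admission_mean, n), 0)
    p_re = expit(lp + config.readmission_intercept_shift)
    tot_ep = int(n_ep.sum())
    first_off = np.floor(r_out.random(n) * np.maximum(fu_end - diag, 1)).astype(np.int64)
    u_re = r_out.random(tot_ep)
    gap_re = r_out.integers(1, 31, tot_ep)
    gap_far = r_out.integers(31, 330, tot_ep)
    los = 2 + r_out.poisson(4.0, tot_ep)
    u_cat = r_out.random(tot_ep)
    u_mrd = r_out.random(tot_ep)
    mrd_copd = r_out.integers(0, len(COPD_CODES), tot_ep)
    mrd_other = r_out.integers(0, len(OTHER_CODES), tot_ep)
    sec_idx = r_out.integers(0, len(OTHER_CODES), tot_ep)
    u_hospital = r_out.random(n)

    ep_pat: list[int] = []
    ep_admit: list[int] = []
    ep_dis: list[int] = []
    ep_cat: list[str] = []
    ep_mrd: list[str] = []
    ep_sec: list[str] = []
    ep_died: list[bool] = []
    death_final = death_day.copy()
    cursor = 0
    for i in np.nonzero(n_ep)[0]:
        base = cursor
        cursor += int(n_ep[i])
        rows: list[list] = []
        prev_dis = None
        admit = int(diag[i] + first_off[i])
        for e in range(int(n_ep[i])):
            idx = base + e
            if prev_dis is not None:
                if u_re[idx] < p_re[i]:
                    admit, cat = prev_dis + int(gap_re[idx]), "emergent"
                else:
                    admit = prev_dis + int(gap_far[idx])
                    cat = _draw_category(u_cat[idx])
            else:
                cat = _draw_category(u_cat[idx])
            if admit >= fu_end[i]:
                break
            dis = admit + int(los[idx])
            mrd = (
                COPD_CODES[mrd_copd[idx]]
                if u_mrd[idx] < 0.30
                else OTHER_CODES[mrd_other[idx]]
            )
            rows.append([admit, dis, cat, mrd, OTHER_CODES[sec_idx[idx]], False])
            prev_dis = dis
        d = death_final[i]
        if not np.isnan(d):
            if rows and d <= diag[i] + horizon and u_hospital[i] < 0.55:
                rows[-1][1] = min(rows[-1][1], max(int(d), rows[-1][0] + 1))
                rows[-1][5] = True
                death_final[i] = rows[-1][1]
            else:
                kept_rows = []
                for row in rows:
                    if row[0] > d:
                        continue
                    if row[1] > d:
                        row[1] = max(int(d), row[0] + 1)
                        row[5] = True
                    kept_rows.append(row)
                rows = kept_rows
        for row in rows:
            ep_pat.append(i)
            ep_admit.append(row[0])
            ep_dis.append(row[1])
            ep_cat.append(row[2])
            ep_mrd.append(row[3])
            ep_sec.append(row[4])
            ep_died.append(row[5])

    # ----- ED records -----------------------------------------------------
    ep_pat_a = np.asarray(ep_pat, dtype=np.int64)
    ep_admit_a = np.asarray(ep_admit, dtype=np.int64)
    ep_cat_a = np.asarray(ep_cat, dtype=object)
    ep_mrd_a = np.asarray(ep_mrd, dtype=object)
    emergent = ep_cat_a == "emergent"
    linked = emergent & (r_ed.random(emergent.size) < 0.85)
    ed_pat = list(ep_pat_a[linked])
    ed_day = list(ep_admit_a[linked])
    ed_code = list(ep_mrd_a[linked])
    ed_admitted = [True] * int(linked.sum())
    ed_sched = list(r_ed.random(int(linked.sum())) < 0.02)

    p_ed = expit(lp + config.ed_intercept_shift)
    n_ed0 = np.where(r_ed.random(n) < p_ed, 1 + r_ed.poisson(1.8, n), 0)
    tot_ed0 = int(n_ed0.sum())
    pat0 = np.repeat(np.arange(n), n_ed0)
    day0 = diag[pat0] + np.floor(
        r_ed.random(tot_ed0) * np.maximum(fu_end - diag, 1)[pat0]
    ).astype(np.int64)
    copd0 = r_ed.random(tot_ed0) < 0.30
    code0 = np.where(
        copd0,
        np.take(np.array(COPD_CODES, dtype=object), r_ed.integers(0, len(COPD_CODES), tot_ed0)),
        np.take(np.array(OTHER_CODES, dtype=object), r_ed.integers(0, len(OTHER_CODES), tot_ed0)),
    )
    sched0 = r_ed.random(tot_ed0) < 0.01
    ed_pat += list(pat0)
    ed_day += list(day0)
    ed_code += list(code0)
    ed_admitted += [False] * tot_ed0
    ed_sched += list(sched0)

    # ----- assemble tables ------------------------------------------------
    persons = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_date": _iso(birth),
            "sex": sex,
            "death_date": _iso(death_final),
            "latitude": lat,
            "longitude": lon,
            "income_quintile": quintile,
            "dependency": marg[:, 0],
            "material_deprivation": marg[:, 1],
            "ethnic_concentration": marg[:, 2],
            "residential_instability": marg[:, 3],
            "marginalization_composite": marg_comp,
            "rural": rural,
            "adg_score": adg,
            "coverage_start": _iso(cov_start),
            "coverage_end": _iso(cov_end),
            "ontario_resident": resident,
        }
    )

    claims = pd.DataFrame(
        {
            "patient_id": pid[pat_rep[keep]],
            "physician_id": prov_ids[prov_of_visit[keep]],
            "specialty": prov_spec[prov_of_visit[keep]],
            "service_date": _iso(visit_day[keep]),
            "diagnosis_code": code[keep],
            "setting": setting[keep],
        }
    )
    if prior_rows.size:
        # the pre-window claim goes to the provider of the first visit so
        # degenerate concentration still yields a single physician
        prior_prov = prov_of_visit[starts[prior_rows]]
        prior_claims = pd.DataFrame(
            {
                "patient_id": pid[prior_rows],
                "physician_id": prov_ids[prior_prov],
                "specialty": prov_spec[prior_prov],
                "service_date": _iso(rec0 - prior_gap),
                "diagnosis_code": np.take(np.array(COPD_CODES, dtype=object), prior_code),
                "setting": "outpatient",
            }
        )
        claims = pd.concat([claims, prior_claims], ignore_index=True)
    claims = claims.sort_values(
        ["patient_id", "service_date", "physician_id"], kind="mergesort"
    ).reset_index(drop=True)

    discharges = pd.DataFrame(
        {
            "patient_id": pid[ep_pat_a] if ep_pat_a.size else pd.Series(dtype=object),
            "admit_date": _iso(ep_admit_a) if ep_pat_a.size else pd.Series(dtype=object),
            "discharge_date": _iso(np.asarray(ep_dis, dtype=np.int64)) if ep_pat_a.size else pd.Series(dtype=object),
            "mrd_code": ep_mrd_a if ep_pat_a.size else pd.Series(dtype=object),
            "secondary_codes": np.asarray(ep_sec, dtype=object) if ep_pat_a.size else pd.Series(dtype=object),
            "admission_category": ep_cat_a if ep_pat_a.size else pd.Series(dtype=object),
            "died_in_hospital": np.asarray(ep_died, dtype=bool) if ep_pat_a.size else pd.Series(dtype=bool),
        }
    )
    discharges = discharges.sort_values(
        ["patient_id", "admit_date"], kind="mergesort"
    ).reset_index(drop=True)

    ed_visits = pd.DataFrame(
        {
            "patient_id": pid[np.asarray(ed_pat, dtype=np.int64)] if ed_pat else pd.Series(dtype=object),
            "visit_date": _iso(np.asarray(ed_day, dtype=np.int64)) if ed_pat else pd.Series(dtype=object),
            "diagnosis_code": np.asarray(ed_code, dtype=object) if ed_pat else pd.Series(dtype=object),
            "admitted": np.asarray(ed_admitted, dtype=bool) if ed_pat else pd.Series(dtype=bool),
            "scheduled": np.asarray(ed_sched, dtype=bool) if ed_pat else pd.Series(dtype=bool),
        }
    )
    ed_visits = ed_visits.sort_values(
        ["patient_id", "visit_date"], kind="mergesort"
    ).reset_index(drop=True)

    providers = pd.DataFrame(
        {
            "physician_id": prov_ids,
            "specialty": prov_spec,
            "office_latitude": prov_lat,
            "office_longitude": prov_lon,
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "true_n_visits": agg["N"].to_numpy(np.int64),
            "true_upc": np.round(upc_t, 6),
            "true_coc": np.round(coc_t, 6),
            "true_secon": np.round(secon_t, 6),
            "true_fp_share": np.round(fp_share_t, 6),
            "true_predominant_group": pred_t,
            "true_low_coci": low_t,
            "p_admission": np.round(p_adm, 6),
        }
    )

    return {
        "persons": persons,
        "claims": claims,
        "discharges": discharges,
        "ed_visits": ed_visits,
        "providers": providers,
        "truth": truth,
    }


def write_dataset(tables: Mapping[str, pd.DataFrame], outdir) -> None:
    """Write the generated tables as CSV files under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
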