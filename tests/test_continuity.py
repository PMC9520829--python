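"""Continuity indices: worked examples, independent oracles, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concare import (
    VisitSequence,
    build_visit_sequences,
    coc,
    compute_profiles,
    classify_predominant_provider,
    dichotomize_coci,
    haversine_km,
    secon,
    upc,
)
from concare.errors import UndefinedIndexError

provider_sequences = st.lists(st.integers(0, 4), min_size=2, max_size=12)


def pair_concordance(providers):
    """Brute-force oracle: probability that two distinct visits drawn
    without replacement share a provider, by enumerating all pairs."""
    pairs = list(itertools.combinations(providers, 2))
    return sum(a == b for a, b in pairs) / len(pairs)


def seq_of(providers, groups=None):
    groups = groups or ["FP"] * len(providers)
    visits = [(f"2010-01-{i+1:02d}", p, g) for i, (p, g) in enumerate(zip(providers, groups))]
    return VisitSequence("P0000001", visits)


@pytest.mark.parametrize(
    "providers, expected",
    [
        (list("AAAA"), 1.0),        # one provider delivers all care
        (list("AAB"), 2 / 3),       # counts (2,1)
        (list("ABCD"), 0.25),       # uniform: 1/k
    ],
)
def test_upc_examples(providers, expected):
    assert upc(seq_of(providers)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "providers, expected",
    [
        (list("ABCD"), 0.0),        # every visit a different provider
        (list("AAAA"), 1.0),        # all visits one provider
        (list("AABB"), 1 / 3),      # counts (2,2): 2 concordant of C(4,2)=6 pairs
    ],
)
def test_coc_examples(providers, expected):
    assert coc(seq_of(providers)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "providers, expected",
    [
        (list("ABAB"), 0.0),        # strict alternation between 2 providers
        (list("AAA"), 1.0),         # unbroken run
        (list("AABB"), 2 / 3),      # 2 matching adjacent pairs of 3
    ],
)
def test_secon_examples(providers, expected):
    assert secon(seq_of(providers)) == pytest.approx(expected)


@pytest.mark.parametrize("fn", [coc, secon])
def test_indices_undefined_below_two_visits(fn):
    with pytest.raises(UndefinedIndexError):
        fn(seq_of(["A"]))
    with pytest.raises(UndefinedIndexError):
        upc(VisitSequence("P0000001", []))


@settings(derandomize=True, max_examples=200, deadline=None)
@given(provider_sequences)
def test_coc_equals_pair_concordance_oracle(providers):
    """COC must equal exhaustive pair-concordance enumeration."""
    assert coc(providers) == pytest.approx(pair_concordance(providers), abs=1e-12)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(provider_sequences)
def test_coc_bounded_by_upc(providers):
    """COC <= UPC always; equality exactly when one provider is seen."""
    c, u = coc(providers), upc(providers)
    assert c <= u + 1e-12
    if len(set(providers)) == 1:
        assert c == pytest.approx(u)
    else:
        assert c < u


@settings(derandomize=True, max_examples=200, deadline=None)
@given(provider_sequences, st.randoms(use_true_random=False))
def test_permutation_invariance(providers, rnd):
    """UPC and COC ignore visit order; SECON does not (witness below)."""
    shuffled = list(providers)
    rnd.shuffle(shuffled)
    assert coc(shuffled) == pytest.approx(coc(providers))
    assert upc(shuffled) == pytest.approx(upc(providers))


def test_secon_is_order_dependent_witness():
    assert secon(list("AABB")) != secon(list("ABAB"))


@settings(derandomize=True, max_examples=200, deadline=None)
@given(provider_sequences)
def test_secon_maximum_over_orderings(providers):
    """SECON <= (N - k) / (N - 1), attained by contiguous grouping."""
    n, k = len(providers), len(set(providers))
    assert secon(providers) <= (n - k) / (n - 1) + 1e-12
    grouped = sorted(providers)
    assert secon(grouped) == pytest.approx((n - k) / (n - 1))


@pytest.mark.parametrize("providers", [list("AAB"), list("ABCD"), list("AABBB")])
def test_duplication_moves_coc_toward_concentration(providers):
    """Replicating the provider pattern m times leaves UPC unchanged and
    moves COC monotonically toward the visit-share concentration sum."""
    u0 = upc(providers)
    cocs = [coc(providers * m) for m in range(1, 6)]
    assert all(upc(providers * m) == pytest.approx(u0) for m in range(1, 6))
    assert all(b >= a - 1e-12 for a, b in zip(cocs, cocs[1:]))
    limit = sum((providers.count(p) / len(providers)) ** 2 for p in set(providers))
    assert abs(cocs[-1] - limit) < abs(cocs[0] - limit) + 1e-12


def test_predominant_provider_classification():
    fp8sp2 = seq_of(list("ABCDEFGHIJ"), ["FP"] * 8 + ["RESP"] * 2)
    assert classify_predominant_provider(fp8sp2) == ("FP", 0.8)
    tie = seq_of(list("ABCDEFGHIJ"), ["FP"] * 5 + ["RESP"] * 5)
    assert classify_predominant_provider(tie)[0] == "FP"  # documented tie-break
    sp_heavy = seq_of(list("ABCDEFGHIJ"), ["FP"] * 1 + ["RESP"] * 9)
    assert classify_predominant_provider(sp_heavy) == ("SP", 0.1)


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def test_haversine_known_values():
    assert haversine_km(45.0, -75.0, 45.0, -75.0) == 0.0
    # one degree of latitude at the equator: R * pi / 180
    assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.1949, abs=1e-3)
    # antipodal points: half the great circle, pi * R
    assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(np.pi * 6371.0, rel=1e-6)


def test_haversine_rejects_bad_coordinates():
    with pytest.raises(ValueError, match="latitude"):
        haversine_km(95.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="longitude"):
        haversine_km(0.0, 200.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# sequence construction from claims
# ---------------------------------------------------------------------------

def _mini_cohort(followup_end="2011-01-01"):
    return pd.DataFrame(
        {
            "patient_id": ["P0000001"],
            "index_date": ["2010-01-01"],
            "followup_end": [followup_end],
            "eligible": [True],
        }
    )


def _claims(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "physician_id", "specialty", "service_date", "setting"]
    )


def test_same_day_same_physician_claims_collapse():
    claims = _claims(
        [["P0000001", "F1", "FP", "2010-02-01", "outpatient"]] * 3
        + [["P0000001", "F1", "FP", "2010-03-01", "outpatient"]]
    )
    seqs = build_visit_sequences(claims, _mini_cohort())
    assert seqs["P0000001"].N == 2


def test_claims_outside_window_are_excluded():
    claims = _claims(
        [
            ["P0000001", "F1", "FP", "2009-12-31", "outpatient"],  # index - 1 day
            ["P0000001", "F1", "FP", "2010-01-01", "outpatient"],
            ["P0000001", "F1", "FP", "2011-01-01", "outpatient"],  # followup_end
        ]
    )
    seqs = build_visit_sequences(claims, _mini_cohort())
    assert seqs["P0000001"].N == 1


def test_six_visits_two_physicians_counts():
    rows = [
        ["P0000001", "F1" if i % 2 else "F2", "FP", f"2010-0{i+1}-15", "outpatient"]
        for i in range(6)
    ]
    seqs = build_visit_sequences(_claims(rows), _mini_cohort())
    seq = seqs["P0000001"]
    assert (seq.N, seq.k) == (6, 2)


def test_vectorized_profiles_agree_with_sequence_functions(tables, cohort, profiles):
    """The table-level profile computation must match the per-sequence
    index functions on every assessable patient."""
    seqs = build_visit_sequences(tables["claims"], cohort)
    checked = 0
    for _, row in profiles.iterrows():
        seq = seqs[row["patient_id"]]
        if seq.N < 2:
            continue
        assert row["n_visits"] == seq.N
        assert row["upc"] == pytest.approx(upc(seq))
        assert row["coc"] == pytest.approx(coc(seq))
        assert row["secon"] == pytest.approx(secon(seq))
        group, share = classify_predominant_provider(seq)
        assert row["predominant_group"] == group
        assert row["fp_visit_share"] == pytest.approx(share)
        checked += 1
    assert checked > 100


def test_dichotomize_median_cut_conventions():
    base = pd.DataFrame(
        {
            "patient_id": list("abcd"),
            "n_visits": [10, 10, 10, 10],
            "coc": [0.2, 0.4, 0.6, 0.8],
        }
    )
    out = dichotomize_coci(base)
    assert list(out["coci_category"]) == ["low", "low", "high", "high"]
    tied = base.assign(coc=[0.5] * 4)
    assert (dichotomize_coci(tied)["coci_category"] == "low").all()
    few = base.assign(n_visits=[10, 10, 10, 3])
    assert dichotomize_coci(few)["coci_category"].iloc[3] == "not_assessed"


def test_pipeline_category_matches_generator_truth(tables, profiles):
    """Away from the exact median, the pipeline's low/high call must agree
    with the generator's planted category."""
    merged = profiles.merge(tables["truth"], on="patient_id")
    merged = merged[merged["coci_category"].isin(["low", "high"])]
    med = profiles.attrs["coc_median"]
    away = merged[np.abs(merged["true_coc"] - med) > 1e-9]
    agree = (away["coci_category"] == "low") == away["true_low_coci"]
    assert agree.mean() > 0.97


def test_distance_column_present_and_sane(profiles):
    d = profiles["distance_km"].dropna()
    assert len(d) > 0
    assert (d >= 0).all()
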