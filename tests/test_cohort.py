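"""Inclusion/exclusion rules, transfer linkage, outcome, sampling, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import birth_for_age, bundle_from, make_bene, make_claim
from rsmrpipe.cohort import (
    CohortSpec,
    apply_inclusion_exclusion,
    attach_outcome,
    build_cohort,
    link_transfers,
    matches_code_set,
    select_one_episode_per_patient,
    split_cohort,
)

SPEC = CohortSpec(seed=0)
T0 = 500  # a generic index admission day with full lookback coverage


def clean_pair(i, *, age=78.0, admit=T0, discharge=None, principal="486",
               secondary="", disposition="alive", ffs_start=-400,
               mc=(np.nan, np.nan), death=np.nan, hosp="H01"):
    bid, cid = f"B{i:02d}", f"C{i:02d}"
    if discharge is None:
        discharge = admit + 5
    bene = make_bene(bid, birth=birth_for_age(age, admit), ffs_start=ffs_start,
                     mc=mc, death=death)
    claim = make_claim(cid, bid, hosp, admit, discharge, principal=principal,
                       secondary=secondary, disposition=disposition)
    return bene, claim


def test_twelve_admission_toy_table():
    """Hand-enumerated audit: 2 under-age, 2 managed-care, 1 secondary-only,
    2 first-day live discharges (1 AMA, retained), 5 clean -> 6 retained."""
    rows = [
        clean_pair(1, age=60.0),                             # under age
        clean_pair(2, age=65.9),                             # under age (boundary)
        clean_pair(3, mc=(T0 - 200, T0 - 100)),              # managed care in lookback
        clean_pair(4, mc=(T0 - 400, T0 - 365)),              # managed care at window edge
        clean_pair(5, principal="038.9", secondary="486"),   # pneumonia secondary only
        clean_pair(6, discharge=T0 + 1, disposition="alive"),  # first-day live
        clean_pair(7, discharge=T0 + 1, disposition="ama"),  # first-day AMA: retained
        clean_pair(8),
        clean_pair(9, principal="482.41"),
        clean_pair(10, principal="487.0"),
        clean_pair(11, age=66.1),
        clean_pair(12, principal="481", death=T0 + 10, disposition="dead"),
    ]
    bundle = bundle_from([b for b, _ in rows], [c for _, c in rows])
    kept, tally = apply_inclusion_exclusion(bundle, SPEC)
    assert len(kept) == 6
    assert set(kept["claim_id"]) == {"C07", "C08", "C09", "C10", "C11", "C12"}
    assert tally.counts["under_age"] == 2
    assert tally.counts["managed_care"] == 2
    assert tally.counts["secondary_only"] == 1
    assert tally.counts["first_day_live"] == 1
    assert tally.included + sum(tally.counts.values()) == 12


def test_empty_bundle_empty_output():
    bundle = bundle_from([], [])
    kept, tally = apply_inclusion_exclusion(bundle, SPEC)
    assert kept.empty
    assert tally.included == 0 and sum(tally.counts.values()) == 0


def test_same_day_death_retained():
    """The first-day rule excludes only live non-AMA discharges."""
    b, c = clean_pair(1, discharge=T0, disposition="dead", death=T0)
    kept, _ = apply_inclusion_exclusion(bundle_from([b], [c]), SPEC)
    assert len(kept) == 1


def test_first_day_transfer_out_retained():
    b, c = clean_pair(1, discharge=T0 + 1, disposition="transferred")
    kept, _ = apply_inclusion_exclusion(bundle_from([b], [c]), SPEC)
    assert len(kept) == 1


def test_incomplete_lookback_excluded():
    b, c = clean_pair(1, ffs_start=T0 - 100)
    kept, tally = apply_inclusion_exclusion(bundle_from([b], [c]), SPEC)
    assert kept.empty and tally.counts["incomplete_lookback"] == 1


def test_exclusion_precedence_first_rule_wins():
    # under-age AND managed care: attributed to age (first in precedence)
    b, c = clean_pair(1, age=60.0, mc=(T0 - 200, T0 - 100))
    _, tally = apply_inclusion_exclusion(bundle_from([b], [c]), SPEC)
    assert tally.counts["under_age"] == 1
    assert tally.counts["managed_care"] == 0


def test_code_set_patterns():
    assert matches_code_set("482.41", SPEC.code_patterns)
    assert matches_code_set("483.0", SPEC.code_patterns)
    assert matches_code_set("487.0", SPEC.code_patterns)
    assert not matches_code_set("487.1", SPEC.code_patterns)
    assert not matches_code_set("480.1", SPEC.code_patterns)
    viral = CohortSpec(include_viral_codes=True)
    assert matches_code_set("480.1", viral.code_patterns)


def _linked(admissions_spec):
    """admissions_spec: list of (admit, discharge, hosp, disposition)."""
    benes, claims = [], []
    b = make_bene("B01", birth=birth_for_age(80, admissions_spec[0][0]))
    benes.append(b)
    for k, (a, d, h, disp) in enumerate(admissions_spec):
        claims.append(make_claim(f"C{k:02d}", "B01", h, a, d, disposition=disp))
    bundle = bundle_from(benes, claims)
    kept, _ = apply_inclusion_exclusion(bundle, SPEC)
    return link_transfers(kept, SPEC)


def test_transfer_gap_one_merges_and_attributes_to_first_hospital():
    eps = _linked([(500, 505, "H01", "transferred"), (506, 512, "H02", "alive")])
    assert len(eps) == 1
    assert eps.iloc[0]["hospital_id"] == "H01"
    assert eps.iloc[0]["index_admission_day"] == 500
    assert eps.iloc[0]["n_claims"] == 2


def test_gap_two_days_is_readmission():
    eps = _linked([(500, 505, "H01", "alive"), (507, 512, "H02", "alive")])
    assert len(eps) == 2


def test_three_hospital_chain_merges_transitively():
    eps = _linked(
        [(500, 504, "H01", "transferred"),
         (504, 508, "H02", "transferred"),
         (509, 515, "H03", "alive")]
    )
    assert len(eps) == 1
    assert eps.iloc[0]["n_claims"] == 3
    assert eps.iloc[0]["hospital_id"] == "H01"


def test_overlapping_stays_raise():
    with pytest.raises(ValueError, match="ambiguous"):
        _linked([(500, 510, "H01", "alive"), (505, 512, "H02", "alive")])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(gap=st.integers(min_value=0, max_value=10))
def test_transfer_boundary_property(gap):
    """gap <= 1 merges, gap >= 2 never merges."""
    eps = _linked([(500, 505, "H01", "alive"), (505 + gap, 520 + gap, "H02", "alive")])
    assert len(eps) == (1 if gap <= 1 else 2)


def test_outcome_window_boundaries():
    benes = [
        make_bene("B01", birth=birth_for_age(80, 500), death=530.0),
        make_bene("B02", birth=birth_for_age(80, 500), death=531.0),
        make_bene("B03", birth=birth_for_age(80, 500)),
    ]
    claims = [make_claim(f"C0{i}", f"B0{i}", "H01", 500, 506) for i in (1, 2, 3)]
    bundle = bundle_from(benes, claims)
    kept, _ = apply_inclusion_exclusion(bundle, SPEC)
    eps = attach_outcome(link_transfers(kept, SPEC), bundle)
    out = eps.set_index("beneficiary_id")["outcome"]
    assert out["B01"] == 1  # death on day 30
    assert out["B02"] == 0  # day 31
    assert out["B03"] == 0  # no death date


def test_death_before_admission_is_data_error():
    benes = [make_bene("B01", birth=birth_for_age(80, 500), death=400.0)]
    claims = [make_claim("C01", "B01", "H01", 500, 506)]
    bundle = bundle_from(benes, claims)
    kept, _ = apply_inclusion_exclusion(bundle, SPEC)
    with pytest.raises(ValueError, match="death date before"):
        attach_outcome(link_transfers(kept, SPEC), bundle)


def _three_episode_frame():
    return pd.DataFrame(
        {
            "episode_id": ["E1", "E2", "E3"],
            "beneficiary_id": ["B01"] * 3,
            "hospital_id": ["H01", "H02", "H03"],
            "index_admission_day": [400, 500, 600],
            "outcome": [0, 0, 1],
        }
    )


def test_one_per_patient_selection_uniform():
    eps = _three_episode_frame()
    picks = {"E1": 0, "E2": 0, "E3": 0}
    reps = 3000
    for s in range(reps):
        sel = select_one_episode_per_patient(eps, seed=s)
        assert len(sel) == 1
        picks[sel.iloc[0]["episode_id"]] += 1
    se = np.sqrt((1 / 3) * (2 / 3) / reps)
    for e in picks:
        assert abs(picks[e] / reps - 1 / 3) < 3 * se


def test_one_per_patient_identity_and_determinism():
    eps = _three_episode_frame().assign(beneficiary_id=["B1", "B2", "B3"])
    sel = select_one_episode_per_patient(eps, seed=1)
    assert len(sel) == 3
    a = select_one_episode_per_patient(_three_episode_frame(), seed=5)
    b = select_one_episode_per_patient(_three_episode_frame(), seed=5)
    pd.testing.assert_frame_equal(a, b)


def _cohort_frame(counts):
    rows = []
    i = 0
    for h, n in counts.items():
        for _ in range(n):
            rows.append({"episode_id": f"E{i:03d}", "beneficiary_id": f"B{i:03d}",
                         "hospital_id": h, "outcome": 0})
            i += 1
    return pd.DataFrame(rows)


def test_split_even_odd_and_degenerate():
    cohort = _cohort_frame({"H01": 10, "H02": 1, "H03": 3})
    der, val = split_cohort(cohort, CohortSpec(seed=2))
    by = der.groupby("hospital_id").size()
    assert by["H01"] == 5
    assert by["H02"] == 1  # single case goes to derivation
    assert by["H03"] == 2  # ceiling rule
    # partition
    assert set(der["episode_id"]) | set(val["episode_id"]) == set(cohort["episode_id"])
    assert set(der["episode_id"]) & set(val["episode_id"]) == set()

    der_all, val_none = split_cohort(cohort, CohortSpec(split_fraction=1.0))
    assert len(val_none) == 0 and len(der_all) == len(cohort)


def test_planted_exclusions_recovered_exactly(small_dataset):
    cfg, bundle, truth = small_dataset
    cohort, tally = build_cohort(bundle, CohortSpec(seed=cfg.seed))
    planted = truth.planted.groupby("rule")["beneficiary_id"].nunique()
    assert tally.counts["managed_care"] == planted["managed_care"]
    assert tally.counts["incomplete_lookback"] == planted["incomplete_lookback"]
    assert tally.counts["secondary_only"] == planted["secondary_only"]
    assert tally.counts["first_day_live"] == planted["first_day_live"]
    assert tally.counts["under_age"] == planted["under_age"]
    # readmissions give 2 episodes each -> one dropped per patient by sampling
    assert tally.counts["multiple_admission"] == planted["readmission"]
    # transfer chains merged: their beneficiaries appear exactly once
    tc = truth.planted.loc[truth.planted["rule"] == "transfer_chain", "beneficiary_id"]
    assert cohort["beneficiary_id"].isin(set(tc)).sum() == planted["transfer_chain"]
    # AMA first-day cases retained
    ama = truth.planted.loc[truth.planted["rule"] == "first_day_ama", "beneficiary_id"]
    assert cohort["beneficiary_id"].isin(set(ama)).sum() == planted["first_day_ama"]


def test_episode_partition_of_retained_admissions(small_dataset):
    cfg, bundle, _ = small_dataset
    spec = CohortSpec(seed=cfg.seed)
    kept, _ = apply_inclusion_exclusion(bundle, spec)
    eps = link_transfers(kept, spec)
    claim_lists = [e.split(";") for e in eps["claim_ids"]]
    flat = [c for lst in claim_lists for c in lst]
    assert sorted(flat) == sorted(kept["claim_id"])
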