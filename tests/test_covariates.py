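"""Code mapping, matrix assembly windows, filtering, VIF, chart matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import birth_for_age, bundle_from, make_bene, make_claim
from rsmrpipe.cohort import CohortSpec, build_cohort
from rsmrpipe.covariates import (
    ConditionMapping,
    CovariateMatrix,
    build_candidate_matrix,
    default_mapping,
    frequency_filter,
    map_codes_to_categories,
    prepare_chart_matrix,
    variance_inflation,
)
from rsmrpipe.synthetic import SimulationConfig, generate_dataset

MAPPING = default_mapping()


def toy_mapping():
    rules = pd.DataFrame(
        [("482*", "prefix", "P2"), ("428.0", "exact", "CHF"),
         ("518.81", "exact", "RESP_FAIL")],
        columns=["pattern", "match_type", "category"],
    )
    return ConditionMapping(rules=rules, complication_suspect=frozenset({"RESP_FAIL"}))


@pytest.mark.parametrize(
    "codes,expected",
    [
        (["482.41"], {"P2"}),
        ([], set()),
        (["428.0", "428.0"], {"CHF"}),
        (["999.9"], set()),
        (["482.0", "428.0", "518.81"], {"P2", "CHF", "RESP_FAIL"}),
    ],
)
def test_map_codes_to_categories(codes, expected):
    assert map_codes_to_categories(codes, toy_mapping()) == expected


def _episode_bundle(*, index_secondary="", receiving_secondary=None,
                    encounters=()):
    """One beneficiary; optionally a 2-claim transfer episode."""
    t0 = 600
    benes = [make_bene("B01", birth=birth_for_age(80, t0))]
    claims = [make_claim("C01", "B01", "H01", t0, t0 + 4,
                         secondary=index_secondary,
                         disposition="transferred" if receiving_secondary is not None else "alive")]
    if receiving_secondary is not None:
        claims.append(make_claim("C02", "B01", "H02", t0 + 5, t0 + 10,
                                 secondary=receiving_secondary))
    enc = [("B01", day, code, setting) for day, code, setting in encounters]
    bundle = bundle_from(benes, claims, enc)
    cohort, _ = build_cohort(bundle, CohortSpec(seed=0))
    assert len(cohort) == 1
    return cohort, bundle


def test_suspect_category_not_credited_from_receiving_hospital():
    cohort, bundle = _episode_bundle(receiving_secondary="518.81")
    m = build_candidate_matrix(cohort, bundle, MAPPING)
    assert m.data["RESP_FAIL"].iloc[0] == 0


def test_suspect_category_credited_from_initial_claim():
    cohort, bundle = _episode_bundle(index_secondary="518.81",
                                     receiving_secondary="")
    m = build_candidate_matrix(cohort, bundle, MAPPING)
    assert m.data["RESP_FAIL"].iloc[0] == 1


def test_non_suspect_credited_from_receiving_hospital():
    cohort, bundle = _episode_bundle(receiving_secondary="428.0")
    m = build_candidate_matrix(cohort, bundle, MAPPING)
    assert m.data["CHF"].iloc[0] == 1


@pytest.mark.parametrize(
    "offset,expected",
    [
        (183, 1),   # physician encounter ~6 months prior
        (365, 1),   # window start, inside half-open [t-365, t)
        (366, 0),   # 12 months + 1 day: outside
        (0, 0),     # index-day encounter is not lookback
    ],
)
def test_lookback_window_boundaries(offset, expected):
    t0 = 600
    cohort, bundle = _episode_bundle(
        encounters=[(t0 - offset, "428.0", "physician")]
    )
    m = build_candidate_matrix(cohort, bundle, MAPPING)
    assert m.data["CHF"].iloc[0] == expected


def test_certain_emission_recovers_true_condition_matrix():
    """With emission probability 1 the assembled matrix equals the
    generator's true condition matrix exactly."""
    cfg = SimulationConfig(n_hospitals=15, seed=33, lookback_emission=1.0,
                           transfer_rate=0.05)
    bundle, truth = generate_dataset(cfg)
    cohort, _ = build_cohort(bundle, CohortSpec(seed=33))
    m = build_candidate_matrix(cohort, bundle, default_mapping())
    got = m.data.set_index(cohort.set_index("episode_id")["beneficiary_id"])
    cats = list(truth.true_conditions.columns)
    expected = truth.true_conditions.loc[got.index, cats]
    pd.testing.assert_frame_equal(
        got[cats].astype(np.int8), expected.astype(np.int8)
    )


def test_rebuild_is_idempotent(small_dataset):
    cfg, bundle, _ = small_dataset
    cohort, _ = build_cohort(bundle, CohortSpec(seed=cfg.seed))
    m1 = build_candidate_matrix(cohort, bundle, MAPPING)
    m2 = build_candidate_matrix(cohort, bundle, MAPPING)
    pd.testing.assert_frame_equal(m1.data, m2.data)
    pd.testing.assert_frame_equal(m1.provenance, m2.provenance)
    # provenance closure: every credited column lists at least one source
    credited = [c for c in m1.indicator_columns if m1.data[c].any()]
    with_prov = set(m1.provenance["column"])
    assert set(credited) <= with_prov


def _matrix_from(df: pd.DataFrame) -> CovariateMatrix:
    prov = pd.DataFrame({"column": df.columns, "source": "test"})
    return CovariateMatrix(data=df, provenance=prov)


def test_frequency_filter_boundaries():
    n = 1000
    df = pd.DataFrame(
        {
            "age": np.full(n, 80.0),
            "female": np.zeros(n),
            "rare": np.r_[np.ones(9), np.zeros(n - 9)],       # 0.9%
            "at_threshold": np.r_[np.ones(10), np.zeros(n - 10)],  # exactly 1%
            "common": np.r_[np.ones(300), np.zeros(n - 300)],
        }
    )
    out = frequency_filter(_matrix_from(df), 0.01)
    assert "rare" not in out.data.columns
    assert "at_threshold" in out.data.columns  # strict "< threshold" rule
    assert "common" in out.data.columns
    assert {"age", "female"} <= set(out.data.columns)

    ident = frequency_filter(_matrix_from(df), 0.0)
    assert list(ident.data.columns) == list(df.columns)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(t1=st.floats(0, 0.5), t2=st.floats(0, 0.5))
def test_frequency_filter_monotone(t1, t2):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.random((200, 6)) < [0.005, 0.02, 0.05, 0.2, 0.5, 0.9],
                      columns=[f"c{i}" for i in range(6)]).astype(int)
    lo, hi = sorted([t1, t2])
    cols_hi = set(frequency_filter(_matrix_from(df), hi).data.columns)
    cols_lo = set(frequency_filter(_matrix_from(df), lo).data.columns)
    assert cols_hi <= cols_lo


def test_vif_independent_columns_near_one():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
    vif = variance_inflation(df)
    assert np.allclose(vif, 1.0, atol=0.01)
    assert (vif >= 1.0 - 1e-12).all()


def test_vif_exact_collinearity_flagged_infinite():
    rng = np.random.default_rng(2)
    a = rng.normal(size=500)
    df = pd.DataFrame({"a": a, "dup": a, "c": rng.normal(size=500)})
    vif = variance_inflation(df)
    assert np.isinf(vif["a"]) and np.isinf(vif["dup"])


def test_vif_known_correlation_closed_form():
    """Empirical correlation constructed to be exactly 0.6 ->
    VIF = 1/(1-0.36) = 1.5625 for the two correlated columns."""
    rng = np.random.default_rng(3)
    n = 2000
    z = rng.normal(size=(n, 3))
    z -= z.mean(axis=0)
    q, _ = np.linalg.qr(z)  # exactly orthonormal columns
    x1 = q[:, 0]
    x2 = 0.6 * x1 + np.sqrt(1 - 0.36) * q[:, 1]
    x3 = q[:, 2]
    vif = variance_inflation(pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}))
    assert vif["x1"] == pytest.approx(1.5625, abs=1e-9)
    assert vif["x2"] == pytest.approx(1.5625, abs=1e-9)
    assert vif["x3"] == pytest.approx(1.0, abs=1e-9)


def test_chart_matrix_missing_rules():
    n = 100
    rng = np.random.default_rng(4)
    rec = pd.DataFrame(
        {
            "heavily_missing": np.where(np.arange(n) < 11, np.nan, 1.0),  # 11%
            "lightly_missing": np.where(np.arange(n) < 5, np.nan, 2.0),   # 5%
            "complete": rng.normal(size=n),
            "all_missing": np.full(n, np.nan),
        }
    )
    m = prepare_chart_matrix(rec, 0.10)
    assert "heavily_missing" not in m.data.columns
    assert "all_missing" not in m.data.columns
    assert m.data["lightly_missing_missing"].mean() == pytest.approx(0.05)
    # reference fill: base column is 0 where the dummy fires
    assert (m.data.loc[m.data["lightly_missing_missing"] == 1, "lightly_missing"] == 0).all()
    assert "complete_missing" not in m.data.columns


def test_chart_matrix_no_missingness_identity():
    rec = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
    m = prepare_chart_matrix(rec)
    assert list(m.data.columns) == ["a", "b"]


def test_mapping_round_trip(tmp_path):
    path = tmp_path / "mapping.csv"
    MAPPING.to_csv(path)
    back = ConditionMapping.from_csv(path)
    assert back.categories == MAPPING.categories
    assert back.complication_suspect == MAPPING.complication_suspect
    assert map_codes_to_categories(["482.0", "038.11"], back) == \
        map_codes_to_categories(["482.0", "038.11"], MAPPING)
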