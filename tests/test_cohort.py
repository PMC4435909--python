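"""Cohort handling: outcome rule, eligibility cascade, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from riskval.cohort import (
    add_derived_variables,
    apply_eligibility,
    classify_diabetes_who,
    compute_bmi,
    prevalence,
    stratify,
)
from riskval.errors import DegenerateAnalysisError, MissingOutcomeError


def _blank_roster(n: int) -> pd.DataFrame:
    """Minimal complete roster of healthy records."""
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "sex": ["female"] * n,
            "age": 50.0,
            "height": 1.6,
            "weight": 70.0,
            "bmi": 27.3,
            "waist": 95.0,
            "sbp": 120.0,
            "dbp": 75.0,
            "on_htn_meds": 0.0,
            "smoker": 0.0,
            "corticosteroids": 0.0,
            "fh_mother": 0.0,
            "fh_father": 0.0,
            "fh_sister": 0.0,
            "fh_brother": 0.0,
            "fpg": 5.0,
            "glucose_2h": 6.0,
            "prior_diagnosis": 0.0,
        }
    )


def test_compute_bmi():
    assert compute_bmi(80.0, 2.0) == pytest.approx(20.0)
    assert compute_bmi(72.3, 1.7) == pytest.approx(25.02, abs=0.01)
    with pytest.raises(ValueError):
        compute_bmi(80.0, 0.0)


def test_who_classification_boundaries():
    assert classify_diabetes_who(7.0, 5.0) == 1  # fasting threshold inclusive
    assert classify_diabetes_who(5.0, 11.1) == 1  # 2-h threshold inclusive
    assert classify_diabetes_who(6.9, 11.0) == 0
    # one measurement missing and the other below threshold: indeterminate
    assert classify_diabetes_who(6.9, None) is None
    assert classify_diabetes_who(None, 11.0) is None
    # one measurement missing but the other diagnostic: classifiable
    assert classify_diabetes_who(7.2, None) == 1
    with pytest.raises(MissingOutcomeError):
        classify_diabetes_who(None, float("nan"))


@given(
    fpg=st.floats(0.5, 30),
    g2h=st.floats(0.5, 30),
    bump=st.floats(0, 10),
)
def test_who_classification_monotone(fpg, g2h, bump):
    """Raising either glucose value never flips a positive to negative."""
    base = classify_diabetes_who(fpg, g2h)
    if base == 1:
        assert classify_diabetes_who(fpg + bump, g2h) == 1
        assert classify_diabetes_who(fpg, g2h + bump) == 1


def test_eligibility_published_cascade():
    """1256 records, 173 prior-diagnosed, 346 of the rest missing -> 737."""
    df = _blank_roster(1256)
    df.loc[: 172, "prior_diagnosis"] = 1.0  # 173 rows
    # among the 1083 undiagnosed, knock out required fields in 346 records
    missing_rows = df.index[173 : 173 + 346]
    df.loc[missing_rows[:200], "waist"] = np.nan
    df.loc[missing_rows[200:300], "glucose_2h"] = np.nan
    df.loc[missing_rows[200:300], "fpg"] = np.nan
    df.loc[missing_rows[300:], "fh_mother"] = np.nan
    analysis, log = apply_eligibility(
        df, ["age", "sex", "bmi", "waist", "fh_any", "on_htn_meds"]
    )
    assert log["stage1_prior_diagnosis"] == 173
    assert log["stage2_missing"] == 346
    assert log["n_analysis"] == len(analysis) == 737
    assert log["n_roster"] == 1256


def test_eligibility_identity_and_edge_cases(roster):
    required = ["age", "sex", "bmi", "waist", "fh_any", "smoker", "on_htn_meds",
                "corticosteroids", "sbp", "dbp"]
    analysis, log = apply_eligibility(roster, required)
    assert (
        log["stage1_prior_diagnosis"] + log["stage2_missing"] + len(analysis)
        == len(roster)
    )
    assert analysis["y"].notna().all()

    empty, elog = apply_eligibility(roster.iloc[0:0], required)
    assert len(empty) == 0 and elog["n_roster"] == 0

    allprior = _blank_roster(10)
    allprior["prior_diagnosis"] = 1.0
    out, plog = apply_eligibility(allprior, ["age"])
    assert len(out) == 0 and plog["stage1_prior_diagnosis"] == 10


def test_indeterminate_outcome_excluded():
    df = _blank_roster(3)
    df.loc[0, "glucose_2h"] = np.nan  # fpg 5.0 below threshold -> indeterminate
    df.loc[1, "fpg"] = 7.5
    df.loc[1, "glucose_2h"] = np.nan  # diagnostic on fasting alone
    analysis, log = apply_eligibility(df, ["age"])
    assert len(analysis) == 2
    assert log["stage2_missing"] == 1
    assert analysis["y"].tolist() == [1.0, 0.0]


def test_stratify_boundaries_and_partition(roster):
    analysis, _ = apply_eligibility(roster, ["age", "bmi", "sex"])
    for axis in ("sex", "age_band", "bmi_band"):
        strata = stratify(analysis, axis)
        assert sum(len(s) for s in strata.values()) == len(analysis)
        idx = pd.concat([s["id"] for s in strata.values()])
        assert idx.is_unique

    edge = _blank_roster(2)
    edge["age"] = [59.9, 60.0]
    edge["bmi"] = [24.99, 25.0]
    analysis, _ = apply_eligibility(edge, ["age", "bmi"])
    ages = stratify(analysis, "age_band")
    assert ages["<60"]["age"].tolist() == [59.9]
    assert ages[">=60"]["age"].tolist() == [60.0]
    bmis = stratify(analysis, "bmi_band")
    assert bmis["<25"]["bmi"].tolist() == [24.99]
    assert bmis[">=25"]["bmi"].tolist() == [25.0]


def test_prevalence_published_counts():
    df = _blank_roster(737)
    df.loc[:129, "fpg"] = 8.0  # 130 events
    analysis, _ = apply_eligibility(df, ["age"])
    count, pct = prevalence(analysis)
    assert (count, pct) == (130, 17.6)

    df2 = _blank_roster(737)
    df2.loc[:579, "fpg"] = 8.0  # female-share analogue: 580/737
    analysis2, _ = apply_eligibility(df2, ["age"])
    assert prevalence(analysis2) == (580, 78.7)

    none = _blank_roster(10)
    analysis3, _ = apply_eligibility(none, ["age"])
    assert prevalence(analysis3) == (0, 0.0)

    with pytest.raises(DegenerateAnalysisError):
        prevalence(analysis3.iloc[0:0])


def test_bmi_precedence_recorded_wins():
    df = _blank_roster(2)
    df.loc[0, "bmi"] = 31.0  # inconsistent with height/weight on purpose
    df.loc[1, "bmi"] = np.nan
    out = add_derived_variables(df)
    assert out.loc[0, "bmi"] == 31.0
    assert out.loc[1, "bmi"] == pytest.approx(70.0 / 1.6**2)


def test_family_history_derivations():
    df = _blank_roster(4)
    df.loc[1, ["fh_mother"]] = 1.0
    df.loc[2, ["fh_mother", "fh_sister"]] = 1.0
    df.loc[3, "fh_father"] = np.nan
    out = add_derived_variables(df)
    assert out["fh_category"].tolist()[:3] == ["none", "parent_or_sibling", "parent_and_sibling"]
    assert np.isnan(out.loc[3, "fh_any"])
    assert out.loc[2, "fh_count"] == 2.0
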