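"""Model registry: loading, validation, evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from riskval.cohort import add_derived_variables
from riskval.errors import MissingDataError, SchemaError
from riskval.models import (
    BUNDLED_MODELS,
    ModelSpec,
    PredictorTerm,
    linear_predictor,
    load_all_bundled_models,
    load_bundled_model,
    model_spec_from_dict,
    model_spec_to_dict,
    predict_probability,
    score_cohort,
)

# Predictor groups per bundled model, as published in the validation
# study's model-overview table (raw cohort columns after expanding the
# derived family-history / blood-pressure variables).
GROUPS = {
    "age": {"age"},
    "sex": {"sex"},
    "bmi": {"bmi"},
    "htn": {"on_htn_meds"},
    "family_history": {"fh_mother", "fh_father", "fh_sister", "fh_brother"},
    "wc": {"waist"},
    "smoking": {"smoker"},
    "corticosteroids": {"corticosteroids"},
    "bp": {"sbp", "dbp"},
}

EXPECTED_PREDICTOR_GROUPS = {
    "cambridge": {"age", "sex", "bmi", "htn", "family_history", "smoking", "corticosteroids"},
    "kuwaiti": {"age", "htn", "family_history", "wc"},
    "omani": {"age", "bmi", "family_history", "wc", "bp"},
    "rotterdam_1": {"age", "sex", "bmi", "htn"},
    "finnish_simplified": {
        "age", "sex", "bmi", "htn", "family_history", "smoking", "corticosteroids",
    },
}


@pytest.mark.parametrize("name", BUNDLED_MODELS)
def test_bundled_model_predictor_sets(name):
    """Each bundled model requires exactly its published predictor set."""
    model = load_bundled_model(name)
    base = set(model.required_base_variables)
    grouped = {g for g, cols in GROUPS.items() if cols & base}
    assert grouped == EXPECTED_PREDICTOR_GROUPS[name]
    # and no raw column outside the declared groups
    all_group_cols = set().union(*(GROUPS[g] for g in grouped))
    assert base <= all_group_cols


def _simple_spec(terms, **kw):
    spec = {"name": "toy", "link": "logistic", "intercept": 0.0, "terms": terms}
    spec.update(kw)
    return spec


def test_duplicate_predictor_rejected():
    terms = [
        {"variable": "age", "transform": "identity", "coefficient": 1.0},
        {"variable": "age", "transform": "identity", "coefficient": 2.0},
    ]
    with pytest.raises(SchemaError, match="duplicated predictor"):
        model_spec_from_dict(_simple_spec(terms))


def test_unknown_variable_rejected_with_legal_names():
    terms = [{"variable": "shoe_size", "transform": "identity", "coefficient": 1.0}]
    with pytest.raises(SchemaError, match="legal names"):
        model_spec_from_dict(_simple_spec(terms))


def test_nonincreasing_cuts_rejected():
    terms = [{"variable": "age", "transform": "binned",
              "cuts": [45, 45], "values": [0, 1, 2]}]
    with pytest.raises(SchemaError, match="strictly increasing"):
        model_spec_from_dict(_simple_spec(terms))


def test_bin_value_count_rejected():
    terms = [{"variable": "age", "transform": "binned",
              "cuts": [45, 55], "values": [0, 1]}]
    with pytest.raises(SchemaError, match="bin values"):
        model_spec_from_dict(_simple_spec(terms))


def test_illegal_indicator_category_rejected():
    terms = [{"variable": "sex", "transform": "indicator",
              "category": "other", "coefficient": 1.0}]
    with pytest.raises(SchemaError, match="legal levels"):
        model_spec_from_dict(_simple_spec(terms))


def test_linear_predictor_values():
    zero = model_spec_from_dict(_simple_spec(
        [{"variable": "age", "transform": "identity", "coefficient": 0.0}]))
    assert linear_predictor(zero, {"age": 50}) == 0.0

    single = model_spec_from_dict(_simple_spec(
        [{"variable": "age", "transform": "identity", "coefficient": 2.0}],
        intercept=-1.0))
    assert linear_predictor(single, {"age": 3.0}) == pytest.approx(5.0)

    binned = model_spec_from_dict(_simple_spec(
        [{"variable": "age", "transform": "binned",
          "cuts": [45, 55, 65], "values": [0, 2, 3, 4]}]))
    assert linear_predictor(binned, {"age": 52}) == pytest.approx(2.0)
    # boundary: a value equal to a cut-point falls in the upper bin
    assert linear_predictor(binned, {"age": 55}) == pytest.approx(3.0)


def test_predict_probability_values():
    m = model_spec_from_dict(_simple_spec(
        [{"variable": "age", "transform": "identity", "coefficient": 1.0}]))
    assert predict_probability(m, {"age": 0.0}) == pytest.approx(0.5)
    assert predict_probability(m, {"age": math.log(3)}) == pytest.approx(0.75)
    # limit behaviour: p -> 1 monotonically as LP grows
    seq = [predict_probability(m, {"age": v}) for v in (5.0, 10.0, 20.0, 30.0)]
    assert all(a < b for a, b in zip(seq, seq[1:]))
    assert seq[-1] == pytest.approx(1.0, abs=1e-9)


def test_missing_predictor_named_in_error():
    m = load_bundled_model("kuwaiti")
    with pytest.raises(MissingDataError, match="waist"):
        linear_predictor(m, {"age": 50, "on_htn_meds": 0, "fh_any": 0, "waist": float("nan")})


@given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=40, unique=True))
def test_probability_strictly_monotone_in_lp(grid):
    """Sorting by LP and by predicted probability gives the same order."""
    lps = [v / 100.0 for v in grid]  # spacing >= 0.01 keeps probabilities distinct
    m = model_spec_from_dict(_simple_spec(
        [{"variable": "age", "transform": "identity", "coefficient": 1.0}]))
    probs = [predict_probability(m, {"age": v}) for v in lps]
    order_lp = np.argsort(lps)
    order_p = np.argsort(probs)
    assert list(order_lp) == list(order_p)


def test_evaluation_is_pure(complete_roster):
    m = load_bundled_model("cambridge")
    row = add_derived_variables(complete_roster.head(5)).iloc[0].to_dict()
    assert predict_probability(m, row) == predict_probability(m, row)


def test_vectorised_scoring_matches_rowwise(complete_roster):
    from riskval.cohort import apply_eligibility

    analysis, _ = apply_eligibility(
        complete_roster,
        ["age", "sex", "bmi", "on_htn_meds", "waist", "smoker",
         "corticosteroids", "fh_any", "fh_category", "elevated_bp"],
    )
    sub = analysis.head(100)
    for name in BUNDLED_MODELS:
        model = load_bundled_model(name)
        vec = score_cohort(model, sub)
        rows = np.array([predict_probability(model, r) for _, r in sub.iterrows()])
        np.testing.assert_allclose(vec, rows, rtol=0, atol=1e-14)


def test_spec_round_trip():
    for model in load_all_bundled_models():
        again = model_spec_from_dict(model_spec_to_dict(model))
        assert again == model
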