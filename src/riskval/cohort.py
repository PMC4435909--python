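"""Cohort data model and epidemiological bookkeeping.

A cohort is an ordinary :class:`pandas.DataFrame` whose columns follow the
dictionary in :data:`BASE_COLUMNS`.  Continuous variables are floats in the
units stated there (no automatic unit conversion is ever performed); binary
variables are 0/1 floats so that missing values can be carried as NaN; sex is
the string ``"male"`` or ``"female"``.

This module owns everything that happens to a cohort before any model is
scored:

* the WHO oral-glucose-tolerance-test outcome classification
  (fasting plasma glucose >= 7.0 mmol/L and/or 2-h glucose >= 11.1 mmol/L),
* derived variables (BMI from height and weight, family-history summaries,
  elevated blood pressure),
* the two-stage eligibility cascade (drop previously diagnosed participants,
  then drop records with a missing outcome or missing required predictors),
* subgroup stratification by sex, age band (<60 vs >=60 years) and BMI band
  (<25 vs >=25 kg/m^2), and
* prevalence summaries.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateAnalysisError, MissingOutcomeError, SchemaError

#: WHO diagnostic thresholds (inclusive), mmol/L.
FPG_THRESHOLD = 7.0
GLUCOSE_2H_THRESHOLD = 11.1

#: Subgroup band edges: >= goes to the upper band.
AGE_BAND_EDGE = 60.0
BMI_BAND_EDGE = 25.0

#: Plausible age range accepted by validation (years).
AGE_RANGE = (15.0, 95.0)

#: Column dictionary for raw cohort tables.  Units are fixed at load time.
BASE_COLUMNS: dict[str, str] = {
    "id": "participant identifier (text)",
    "sex": "'male' or 'female'",
    "age": "years",
    "height": "m",
    "weight": "kg",
    "bmi": "kg/m^2 (optional if height and weight are present)",
    "waist": "waist circumference, cm",
    "sbp": "systolic blood pressure, mmHg",
    "dbp": "diastolic blood pressure, mmHg",
    "on_htn_meds": "0/1, currently using antihypertensive medication",
    "smoker": "0/1, current smoker",
    "corticosteroids": "0/1, corticosteroid use",
    "fh_mother": "0/1, mother has diabetes",
    "fh_father": "0/1, father has diabetes",
    "fh_sister": "0/1, sister has diabetes",
    "fh_brother": "0/1, brother has diabetes",
    "fpg": "fasting plasma glucose, mmol/L",
    "glucose_2h": "2-h post-load plasma glucose, mmol/L",
    "prior_diagnosis": "0/1, previously diagnosed diabetes",
    "hdl": "HDL cholesterol, mmol/L (optional)",
    "triglycerides": "triglycerides, mmol/L (optional)",
    "alcohol_ever": "0/1, ever consumed alcohol (optional)",
    "alcohol_current": "0/1, current drinker (optional)",
}

_FH_COLUMNS = ("fh_mother", "fh_father", "fh_sister", "fh_brother")

#: Derived variables available to model specifications, mapped to the raw
#: columns they are computed from.  ``bmi`` is special: a recorded value
#: wins, otherwise it is derived from height and weight.
DERIVED_SOURCES: dict[str, tuple[str, ...]] = {
    "bmi": ("bmi", "height", "weight"),
    "fh_any": _FH_COLUMNS,
    "fh_parent": ("fh_mother", "fh_father"),
    "fh_sibling": ("fh_sister", "fh_brother"),
    "fh_count": _FH_COLUMNS,
    "fh_category": _FH_COLUMNS,
    "elevated_bp": ("sbp", "dbp"),
}

#: Legal categories for categorical variables referenced by indicator terms.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "fh_category": ("none", "parent_or_sibling", "parent_and_sibling"),
}

#: All variable names a model specification may reference.
COHORT_DICTIONARY: frozenset[str] = frozenset(BASE_COLUMNS) | frozenset(DERIVED_SOURCES)


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index, weight (kg) per squared height (m)."""
    if not (weight > 0) or not (height > 0):
        raise ValueError(f"weight and height must be positive, got {weight!r}, {height!r}")
    return weight / height**2


def classify_diabetes_who(fpg: float | None, glucose_2h: float | None) -> int | None:
    """Classify screen-detected diabetes by the WHO OGTT rule.

    Returns 1 if either glucose measurement is at or above its diagnostic
    threshold, 0 if both are present and below threshold, and ``None``
    (indeterminate, treated as a missing outcome) if only one value is
    present and it is below threshold.

    Raises
    ------
    MissingOutcomeError
        If both measurements are missing.
    """
    fpg_missing = fpg is None or (isinstance(fpg, float) and math.isnan(fpg))
    g2_missing = glucose_2h is None or (isinstance(glucose_2h, float) and math.isnan(glucose_2h))
    if fpg_missing and g2_missing:
        raise MissingOutcomeError("both fpg and glucose_2h are missing")
    if not fpg_missing and fpg >= FPG_THRESHOLD:
        return 1
    if not g2_missing and glucose_2h >= GLUCOSE_2H_THRESHOLD:
        return 1
    if fpg_missing or g2_missing:
        return None
    return 0


def outcome_series(df: pd.DataFrame) -> pd.Series:
    """Vectorised WHO classification; NaN marks missing/indeterminate outcomes."""
    fpg = df["fpg"].to_numpy(dtype=float)
    g2 = df["glucose_2h"].to_numpy(dtype=float)
    pos = (fpg >= FPG_THRESHOLD) | (g2 >= GLUCOSE_2H_THRESHOLD)
    neg = (fpg < FPG_THRESHOLD) & (g2 < GLUCOSE_2H_THRESHOLD)
    y = np.full(len(df), np.nan)
    y[pos] = 1.0
    y[neg & ~pos] = 0.0
    return pd.Series(y, index=df.index, name="y")


def add_derived_variables(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``df`` with all derived columns attached.

    A recorded BMI takes precedence over the height/weight derivation; only
    records with a missing BMI and both height and weight present get a
    derived value.
    """
    out = df.copy()
    if "bmi" not in out.columns:
        out["bmi"] = np.nan
    derivable = out["bmi"].isna() & out.get("height", pd.Series(np.nan, index=out.index)).notna() \
        & out.get("weight", pd.Series(np.nan, index=out.index)).notna()
    if derivable.any():
        h = out.loc[derivable, "height"].to_numpy(dtype=float)
        w = out.loc[derivable, "weight"].to_numpy(dtype=float)
        out.loc[derivable, "bmi"] = w / h**2

    fh = out[list(_FH_COLUMNS)].to_numpy(dtype=float)
    any_missing = np.isnan(fh).any(axis=1)
    fh_count = np.nansum(fh, axis=1)
    fh_count[any_missing] = np.nan  # exact count unknowable with a missing relative
    # fh_any is determinate if any relative is 1 or all four are observed.
    fh_any = np.where((fh == 1).any(axis=1), 1.0, np.where(any_missing, np.nan, 0.0))
    parent = out[["fh_mother", "fh_father"]].to_numpy(dtype=float)
    sibling = out[["fh_sister", "fh_brother"]].to_numpy(dtype=float)

    def _group_any(block: np.ndarray) -> np.ndarray:
        pos = (block == 1).any(axis=1)
        miss = np.isnan(block).any(axis=1)
        return np.where(pos, 1.0, np.where(miss, np.nan, 0.0))

    fh_parent = _group_any(parent)
    fh_sibling = _group_any(sibling)
    out["fh_any"] = fh_any
    out["fh_count"] = fh_count
    out["fh_parent"] = fh_parent
    out["fh_sibling"] = fh_sibling
    cat = np.where(
        np.isnan(fh_parent) | np.isnan(fh_sibling),
        None,
        np.where(
            (fh_parent == 1) & (fh_sibling == 1),
            "parent_and_sibling",
            np.where((fh_parent == 1) | (fh_sibling == 1), "parent_or_sibling", "none"),
        ),
    )
    out["fh_category"] = cat
    sbp = out["sbp"].to_numpy(dtype=float)
    dbp = out["dbp"].to_numpy(dtype=float)
    ebp = np.where(
        (sbp >= 140) | (dbp >= 90),
        1.0,
        np.where(np.isnan(sbp) | np.isnan(dbp), np.nan, 0.0),
    )
    out["elevated_bp"] = ebp
    return out


def required_base_columns(required_vars: Iterable[str]) -> list[str]:
    """Expand derived variable names to the raw columns they depend on.

    ``bmi`` expands to itself only: after :func:`add_derived_variables` a
    usable BMI (recorded or derived) lives in the ``bmi`` column.
    """
    cols: list[str] = []
    for v in required_vars:
        if v not in COHORT_DICTIONARY:
            raise SchemaError(f"unknown variable {v!r}; legal names: {sorted(COHORT_DICTIONARY)}")
        if v == "bmi" or v not in DERIVED_SOURCES:
            expanded = (v,)
        else:
            expanded = DERIVED_SOURCES[v]
        for c in expanded:
            if c not in cols:
                cols.append(c)
    return cols


def apply_eligibility(
    roster: pd.DataFrame, required_vars: Iterable[str]
) -> tuple[pd.DataFrame, dict]:
    """Two-stage eligibility filter.

    Stage 1 drops participants with a prior diabetes diagnosis; stage 2 drops
    records with a missing/indeterminate outcome or any missing required
    predictor.  Returns the analysis set (with derived columns and an ``y``
    outcome column attached) and a structured exclusion log.  The identity
    ``len(analysis) + stage1 + stage2 == len(roster)`` always holds.
    """
    required_vars = list(required_vars)
    df = add_derived_variables(roster)
    n_roster = len(df)
    if n_roster == 0:
        log = {
            "n_roster": 0,
            "stage1_prior_diagnosis": 0,
            "stage2_missing": 0,
            "n_analysis": 0,
            "missing_by_variable": {},
            "missing_outcome": 0,
        }
        empty = df.iloc[0:0].copy()
        empty["y"] = pd.Series(dtype=float)
        return empty, log

    prior = df["prior_diagnosis"].to_numpy(dtype=float) == 1
    stage1 = int(prior.sum())
    remaining = df.loc[~prior]

    y = outcome_series(remaining)
    missing_outcome = y.isna()
    derived_needed = [v for v in required_vars if v in remaining.columns or v in DERIVED_SOURCES]
    miss_by_var: dict[str, int] = {}
    any_missing = missing_outcome.to_numpy().copy()
    for v in derived_needed:
        col = remaining[v]
        if col.dtype == object:
            m = col.isna() | (col == None)  # noqa: E711  (object column with None markers)
        else:
            m = col.isna()
        miss_by_var[v] = int(m.sum())
        any_missing |= m.to_numpy()
    stage2 = int(any_missing.sum())
    analysis = remaining.loc[~any_missing].copy()
    analysis["y"] = y.loc[~any_missing]

    log = {
        "n_roster": n_roster,
        "stage1_prior_diagnosis": stage1,
        "stage2_missing": stage2,
        "n_analysis": len(analysis),
        "missing_by_variable": miss_by_var,
        "missing_outcome": int(missing_outcome.sum()),
    }
    return analysis, log


_AXES = ("sex", "age_band", "bmi_band")


def stratify(cohort: pd.DataFrame, axis: str) -> dict[str, pd.DataFrame]:
    """Partition an analysis set along one subgroup axis.

    Axes: ``sex`` (male/female), ``age_band`` (<60 / >=60 years),
    ``bmi_band`` (<25 / >=25 kg/m^2).  Values at the band edge go to the
    upper band.  The returned sub-cohorts are disjoint and exhaustive.
    """
    if axis not in _AXES:
        raise SchemaError(f"unknown subgroup axis {axis!r}; one of {_AXES}")
    if axis == "sex":
        return {
            "male": cohort.loc[cohort["sex"] == "male"],
            "female": cohort.loc[cohort["sex"] == "female"],
        }
    if axis == "age_band":
        v = cohort["age"].to_numpy(dtype=float)
        return {
            "<60": cohort.loc[v < AGE_BAND_EDGE],
            ">=60": cohort.loc[v >= AGE_BAND_EDGE],
        }
    v = cohort["bmi"].to_numpy(dtype=float)
    return {
        "<25": cohort.loc[v < BMI_BAND_EDGE],
        ">=25": cohort.loc[v >= BMI_BAND_EDGE],
    }


def prevalence(cohort: pd.DataFrame) -> tuple[int, float]:
    """Event count and percent prevalence (percent rounded to 1 decimal)."""
    if len(cohort) == 0:
        raise DegenerateAnalysisError("prevalence is undefined on an empty cohort")
    y = cohort["y"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise DegenerateAnalysisError("prevalence requires fully defined outcomes")
    count = int(y.sum())
    return count, round(100.0 * count / len(cohort), 1)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (empty fields are missing values)."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    unknown = [c for c in df.columns if c not in BASE_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown cohort columns {unknown}; dictionary: {sorted(BASE_COLUMNS)}")
    _validate_ranges(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV with empty fields as the missing-value token."""
    cols = [c for c in BASE_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def _validate_ranges(df: pd.DataFrame) -> None:
    age = df.get("age")
    if age is not None:
        bad = age.dropna()
        bad = bad[(bad < AGE_RANGE[0]) | (bad > AGE_RANGE[1])]
        if len(bad):
            raise SchemaError(
                f"{len(bad)} age values outside the plausible range {AGE_RANGE}"
            )
    for col in ("height", "weight", "bmi", "waist", "sbp", "dbp", "fpg", "glucose_2h"):
        if col in df.columns:
            vals = df[col].dropna()
            if (vals <= 0).any():
                raise SchemaError(f"non-positive values in physiological column {col!r}")


def participant_record(row: Mapping) -> dict:
    """Convenience: convert a cohort row (Series/dict) into a plain dict."""
    return dict(row)
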