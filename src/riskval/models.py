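"""Risk-model specifications: loading, validation and evaluation.

A risk model is data, not code: a YAML file declares an intercept, a list of
predictor terms and a probability link, and this module evaluates it.  All
bundled models are logistic in form,

    p = 1 / (1 + exp(-LP)),

where the linear predictor ``LP`` is either ``intercept + sum(term values)``
(regression-style models such as the Cambridge score) or, for integer
point-score models (Omani, simplified Finnish), a documented
score-to-probability link ``LP = a + b * score`` with ``score`` the sum of
the term values.

Term transforms:

``identity``
    coefficient * value (continuous predictors).
``indicator``
    coefficient if the value equals the declared category (booleans are the
    categories ``true``/``false``; sex uses ``male``/``female``).
``binned``
    strictly increasing cut-points and one value per bin; a value equal to a
    cut-point falls in the upper bin.  Used for age bands, BMI classes and
    point-score components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import CATEGORICAL_LEVELS, COHORT_DICTIONARY, required_base_columns
from .errors import FormatError, MissingDataError, SchemaError

_TRANSFORMS = ("identity", "indicator", "binned")
_LINKS = ("logistic", "logistic_score")

#: Names of the five bundled model specifications.
BUNDLED_MODELS = ("cambridge", "kuwaiti", "omani", "rotterdam_1", "finnish_simplified")


@dataclass(frozen=True)
class PredictorTerm:
    """One additive component of a model's linear predictor or score."""

    variable: str
    transform: str
    coefficient: float | None = None
    category: str | None = None
    cuts: tuple[float, ...] | None = None
    values: tuple[float, ...] | None = None

    def evaluate(self, value) -> float:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingDataError(f"missing value for predictor {self.variable!r}")
        if self.transform == "identity":
            return self.coefficient * float(value)
        if self.transform == "indicator":
            return self.coefficient if _matches(value, self.category) else 0.0
        idx = int(np.searchsorted(self.cuts, float(value), side="right"))
        return self.values[idx]


def _matches(value, category: str) -> bool:
    if category in ("true", "false"):
        return bool(value) == (category == "true")
    return str(value) == category


@dataclass(frozen=True)
class ScoreLink:
    """Logistic link mapping an integer score to a probability."""

    intercept: float
    slope: float


@dataclass(frozen=True)
class ModelSpec:
    """A validated, immutable risk-model specification."""

    name: str
    source_ref: str
    terms: tuple[PredictorTerm, ...]
    intercept: float = 0.0
    link: str = "logistic"
    score_link: ScoreLink | None = None
    provenance: str | None = None

    @property
    def required_variables(self) -> tuple[str, ...]:
        """Model-level variable names, in term order, without duplicates."""
        seen: list[str] = []
        for t in self.terms:
            if t.variable not in seen:
                seen.append(t.variable)
        return tuple(seen)

    @property
    def required_base_variables(self) -> tuple[str, ...]:
        """Raw cohort columns needed, with derived variables expanded."""
        return tuple(required_base_columns(self.required_variables))


def linear_predictor(model: ModelSpec, participant: Mapping) -> float:
    """Evaluate the model's linear predictor for one participant record."""
    total = 0.0
    for term in model.terms:
        if term.variable not in participant:
            raise MissingDataError(f"missing value for predictor {term.variable!r}")
        total += term.evaluate(participant[term.variable])
    if model.link == "logistic_score":
        return model.score_link.intercept + model.score_link.slope * total
    return model.intercept + total


def predict_probability(model: ModelSpec, participant: Mapping) -> float:
    """Predicted probability 1 / (1 + exp(-LP)); strictly increasing in LP."""
    lp = linear_predictor(model, participant)
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    e = math.exp(lp)
    return e / (1.0 + e)


def score_cohort(model: ModelSpec, cohort) -> np.ndarray:
    """Vectorised predicted probabilities for every row of an analysis set.

    The cohort must already carry the derived columns
    (:func:`riskval.cohort.add_derived_variables`) and have no missing
    values among the model's predictors.
    """
    n = len(cohort)
    total = np.zeros(n)
    for term in model.terms:
        if term.variable not in cohort.columns:
            raise MissingDataError(f"cohort lacks predictor column {term.variable!r}")
        col = cohort[term.variable]
        if term.transform == "indicator":
            if term.category in ("true", "false"):
                vals = col.to_numpy(dtype=float)
                if np.isnan(vals).any():
                    raise MissingDataError(f"missing value for predictor {term.variable!r}")
                hit = (vals == 1) == (term.category == "true")
            else:
                if col.isna().any():
                    raise MissingDataError(f"missing value for predictor {term.variable!r}")
                hit = col.astype(str).to_numpy() == term.category
            total += np.where(hit, term.coefficient, 0.0)
        else:
            vals = col.to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise MissingDataError(f"missing value for predictor {term.variable!r}")
            if term.transform == "identity":
                total += term.coefficient * vals
            else:
                idx = np.searchsorted(term.cuts, vals, side="right")
                total += np.asarray(term.values)[idx]
    if model.link == "logistic_score":
        lp = model.score_link.intercept + model.score_link.slope * total
    else:
        lp = model.intercept + total
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-lp))


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def model_spec_from_dict(raw: dict) -> ModelSpec:
    """Validate a parsed model-spec mapping; schema violations are rejected."""
    if not isinstance(raw, dict):
        raise FormatError("model spec must be a mapping")
    for key in ("name", "terms"):
        if key not in raw:
            raise FormatError(f"model spec missing required field {key!r}")
    link = raw.get("link", "logistic")
    if link not in _LINKS:
        raise SchemaError(f"unrecognised link {link!r}; one of {_LINKS}")
    score_link = None
    if link == "logistic_score":
        sl = raw.get("score_link")
        if not isinstance(sl, dict) or "intercept" not in sl or "slope" not in sl:
            raise FormatError("logistic_score link requires score_link: {intercept, slope}")
        score_link = ScoreLink(float(sl["intercept"]), float(sl["slope"]))

    terms: list[PredictorTerm] = []
    signatures: set[tuple] = set()
    variables_seen: dict[str, str] = {}
    for i, t in enumerate(raw["terms"]):
        if not isinstance(t, dict) or "variable" not in t or "transform" not in t:
            raise FormatError(f"term #{i}: needs 'variable' and 'transform' fields")
        var = t["variable"]
        if var not in COHORT_DICTIONARY:
            raise SchemaError(
                f"term #{i}: unknown variable {var!r}; legal names: {sorted(COHORT_DICTIONARY)}"
            )
        transform = t["transform"]
        if transform not in _TRANSFORMS:
            raise FormatError(f"term #{i}: unknown transform {transform!r}; one of {_TRANSFORMS}")
        if transform == "binned":
            cuts = tuple(float(c) for c in t.get("cuts", ()))
            values = tuple(float(v) for v in t.get("values", ()))
            if len(cuts) < 1 or any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise SchemaError(f"term #{i} ({var}): cut-points must be strictly increasing")
            if len(values) != len(cuts) + 1:
                raise SchemaError(
                    f"term #{i} ({var}): needs {len(cuts) + 1} bin values, got {len(values)}"
                )
            term = PredictorTerm(var, "binned", cuts=cuts, values=values)
            sig = (var, "binned")
        elif transform == "indicator":
            category = t.get("category")
            if category is None:
                raise FormatError(f"term #{i} ({var}): indicator transform needs a category")
            category = str(category).lower() if isinstance(category, (bool, str)) else category
            legal = CATEGORICAL_LEVELS.get(var, ("true", "false"))
            if category not in legal:
                raise SchemaError(
                    f"term #{i} ({var}): category {category!r} not among legal levels {legal}"
                )
            term = PredictorTerm(
                var, "indicator", coefficient=float(t["coefficient"]), category=category
            )
            sig = (var, "indicator", category)
        else:
            if "coefficient" not in t:
                raise FormatError(f"term #{i} ({var}): identity transform needs a coefficient")
            term = PredictorTerm(var, "identity", coefficient=float(t["coefficient"]))
            sig = (var, "identity")
        if sig in signatures:
            raise SchemaError(f"duplicated predictor term for variable {var!r}")
        # A variable may appear in several indicator terms (dummy coding),
        # but never under two different transforms.
        if var in variables_seen and (variables_seen[var] != transform or transform != "indicator"):
            raise SchemaError(f"duplicated predictor name {var!r} in model spec")
        signatures.add(sig)
        variables_seen[var] = transform
        terms.append(term)

    return ModelSpec(
        name=str(raw["name"]),
        source_ref=str(raw.get("source_ref", "")),
        terms=tuple(terms),
        intercept=float(raw.get("intercept", 0.0)),
        link=link,
        score_link=score_link,
        provenance=raw.get("provenance"),
    )


def load_model_spec(path) -> ModelSpec:
    """Load and validate a model specification from a YAML file."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse model spec {path}: {exc}") from exc
    return model_spec_from_dict(raw)


def load_bundled_model(name: str) -> ModelSpec:
    """Load one of the five bundled model specifications by short name."""
    if name not in BUNDLED_MODELS:
        raise SchemaError(f"unknown bundled model {name!r}; one of {BUNDLED_MODELS}")
    ref = resources.files("riskval").joinpath(f"model_library/{name}.yaml")
    raw = yaml.safe_load(ref.read_text())
    return model_spec_from_dict(raw)


def load_all_bundled_models() -> list[ModelSpec]:
    return [load_bundled_model(name) for name in BUNDLED_MODELS]


def model_spec_to_dict(model: ModelSpec) -> dict:
    """Serialise a ModelSpec back to the documented mapping format."""
    terms = []
    for t in model.terms:
        d: dict = {"variable": t.variable, "transform": t.transform}
        if t.transform == "binned":
            d["cuts"] = list(t.cuts)
            d["values"] = list(t.values)
        else:
            d["coefficient"] = t.coefficient
            if t.transform == "indicator":
                d["category"] = t.category
        terms.append(d)
    out = {
        "name": model.name,
        "source_ref": model.source_ref,
        "link": model.link,
        "intercept": model.intercept,
        "terms": terms,
    }
    if model.score_link is not None:
        out["score_link"] = {
            "intercept": model.score_link.intercept,
            "slope": model.score_link.slope,
        }
    if model.provenance:
        out["provenance"] = model.provenance
    return out


def save_model_spec(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_spec_to_dict(model), fh, sort_keys=False)
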