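"""End-to-end validation pipeline and tabular reporting.

Stages run in a fixed order: eligibility -> scoring -> overall metrics ->
subgroups -> intercept adjustment -> adjusted metrics -> pairwise
C-statistic comparisons -> (optional) multiple-imputation sensitivity.
The result is a plain nested dict (JSON-serialisable, byte-identical
under a fixed seed) mirroring the published performance-table layout:
E/O (95% CI), Brier score, Yates slope, C (95% CI), optimal threshold,
sensitivity, specificity, correctly classified - original and
intercept-adjusted columns per model, plus subgroup blocks per sex, age
band and BMI band.

Display rounding follows the reporting conventions: percentages to whole
numbers, C and E/O to two decimals, Brier/Yates to three; the underlying
JSON keeps full precision.
"""

from __future__ import annotations

import hashlib
import json
from itertools import combinations

import numpy as np
import pandas as pd

from . import __version__
from .cohort import apply_eligibility, prevalence, read_cohort, stratify
from .errors import DegenerateAnalysisError, RiskvalInputError
from .impute import impute_chained, pooled_validation
from .metrics import (
    brier_score,
    c_statistic,
    calibration_curve,
    compare_c_statistics,
    eo_ratio,
    miscalibration_percent,
    optimal_threshold,
    yates_slope,
)
from .models import ModelSpec, load_model_spec, score_cohort
from .recalibrate import apply_intercept_adjustment, fit_intercept_adjustment

_SUBGROUP_AXES = ("sex", "age_band", "bmi_band")

METRIC_ROWS = (
    "E/O (95% CI)",
    "Brier score",
    "Yates slope",
    "C-statistic (95% CI)",
    "Optimal threshold",
    "Sensitivity",
    "Specificity",
    "Correctly classified",
)

#: Sentinel rendered for metrics undefined on a degenerate subgroup.
UNDEFINED = "-"


def _metric_block(p: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> dict:
    """Full performance block for one prediction set; degenerate-safe."""
    block: dict = {"n": int(len(y)), "events": int(y.sum())}
    if len(y) == 0 or y.min() == y.max():
        block["defined"] = False
        return block
    block["defined"] = True
    eo = eo_ratio(p, y)
    mis = miscalibration_percent(eo)
    cs = c_statistic(p, y)
    thr = optimal_threshold(p, y)
    block.update(
        {
            "eo": {"e": eo.e, "o": eo.o, "ratio": eo.ratio,
                   "ci_low": eo.ci_low, "ci_high": eo.ci_high},
            "miscalibration": {
                "direction": mis.direction, "percent": mis.percent,
                "ci_low": mis.ci_low, "ci_high": mis.ci_high,
            },
            "brier": brier_score(p, y),
            "yates_slope": yates_slope(p, y),
            "c": {"value": cs.c, "ci_low": cs.ci_low, "ci_high": cs.ci_high, "se": cs.se},
            "threshold": {
                "value": thr.threshold,
                "sensitivity": thr.sensitivity,
                "specificity": thr.specificity,
                "correctly_classified": thr.correctly_classified,
                "youden_j": thr.youden_j,
            },
        }
    )
    if n_bins is not None and len(y) >= n_bins:
        curve = calibration_curve(p, y, n_bins=n_bins)
        block["calibration_curve"] = {
            "mean_pred": list(curve.mean_predicted),
            "obs_rate": list(curve.observed_rate),
            "count": list(curve.counts),
            "binning": curve.binning,
        }
    return block


def run_validation(
    cohort,
    models,
    *,
    n_bins: int = 10,
    imputation_m: int = 5,
    do_imputation: bool = True,
    seed: int = 0,
    per_model_complete_case: bool = False,
) -> dict:
    """Validate one or more risk models on a cohort.

    Parameters
    ----------
    cohort
        DataFrame or path to a cohort CSV (raw columns).
    models
        Sequence of :class:`ModelSpec` or paths to model-spec files.
    per_model_complete_case
        If True each model is validated on its own complete-case subset
        (changes n per model; the default single common analysis set uses
        the union of all models' predictors).
    """
    if isinstance(cohort, (str, bytes)) or hasattr(cohort, "__fspath__"):
        cohort = read_cohort(cohort)
    specs: list[ModelSpec] = [
        m if isinstance(m, ModelSpec) else load_model_spec(m) for m in models
    ]
    if not specs:
        raise RiskvalInputError("at least one model is required")
    names = [m.name for m in specs]
    if len(set(names)) != len(names):
        raise RiskvalInputError(f"duplicate model names in run: {names}")

    union_vars: list[str] = []
    for spec in specs:
        for v in spec.required_base_variables:
            if v not in union_vars:
                union_vars.append(v)

    run: dict = {
        "software": {"package": "riskval", "version": __version__},
        "seed": int(seed),
        "options": {
            "n_bins": n_bins,
            "imputation_m": imputation_m,
            "per_model_complete_case": per_model_complete_case,
        },
        "cohort_hash": _cohort_hash(cohort),
        "models": names,
    }

    analysis, log = apply_eligibility(cohort, union_vars)
    run["exclusion_log"] = log
    if len(analysis) == 0:
        raise DegenerateAnalysisError("no participants remain after eligibility filtering")
    events, prev_pct = prevalence(analysis)
    run["prevalence"] = {"events": events, "percent": prev_pct, "n": len(analysis)}

    y = analysis["y"].to_numpy(dtype=float)
    per_model: dict[str, dict] = {}
    probs: dict[str, np.ndarray] = {}
    for spec in specs:
        if per_model_complete_case:
            sub, sub_log = apply_eligibility(cohort, spec.required_base_variables)
            p = score_cohort(spec, sub)
            yy = sub["y"].to_numpy(dtype=float)
        else:
            sub, sub_log = analysis, None
            p = score_cohort(spec, analysis)
            yy = y
        probs[spec.name] = p

        original = _metric_block(p, yy, n_bins=n_bins)
        adj = fit_intercept_adjustment(p, yy)
        adjusted_model = apply_intercept_adjustment(spec, adj)
        p_adj = score_cohort(adjusted_model, sub)
        adjusted = _metric_block(p_adj, yy, n_bins=n_bins)
        adjusted["delta"] = adj.delta

        subgroups: dict = {}
        for axis in _SUBGROUP_AXES:
            subgroups[axis] = {}
            for level, grp in stratify(sub, axis).items():
                pg = score_cohort(spec, grp) if len(grp) else np.empty(0)
                yg = grp["y"].to_numpy(dtype=float)
                subgroups[axis][level] = _metric_block(pg, yg)

        per_model[spec.name] = {
            "source_ref": spec.source_ref,
            "original": original,
            "adjusted": adjusted,
            "subgroups": subgroups,
        }
        if sub_log is not None:
            per_model[spec.name]["exclusion_log"] = sub_log
    run["performance"] = per_model

    # Pairwise comparison of C statistics (same subjects; only meaningful
    # on the common analysis set).
    comparisons = []
    if not per_model_complete_case:
        pairs = list(combinations(names, 2))
        n_tests = len(pairs)
        for a, b in pairs:
            cmp_res = compare_c_statistics(probs[a], y, probs[b], y)
            comparisons.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "delta_c": cmp_res.delta,
                    "p_value": cmp_res.p_value,
                    # multiplicity-corrected column, labelled as an extension
                    "p_value_bonferroni": min(1.0, cmp_res.p_value * n_tests),
                }
            )
    run["c_comparisons"] = comparisons

    if do_imputation and imputation_m > 0:
        # Sensitivity stage: impute the stage-1-filtered roster so records
        # excluded for missing data re-enter the analysis.
        roster = cohort.loc[cohort["prior_diagnosis"] != 1]
        imp = impute_chained(roster, m=imputation_m, seed=seed)
        sens: dict = {
            "m": imp.m,
            "cycles": imp.cycles,
            "imputed_variables": list(imp.imputed_variables),
            "n_outcome_imputed": imp.n_outcome_imputed,
            "per_model": {},
        }
        for spec in specs:
            pv = pooled_validation(imp, spec)
            sens["per_model"][spec.name] = {
                "per_dataset_c": list(pv.per_dataset_c),
                "pooled_c": pv.pooled_c,
                "min": pv.c_min,
                "max": pv.c_max,
            }
        run["imputation_sensitivity"] = sens
    return run


def _cohort_hash(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt_block(block: dict) -> list[str]:
    if not block.get("defined"):
        return [UNDEFINED] * len(METRIC_ROWS)
    eo = block["eo"]
    c = block["c"]
    t = block["threshold"]
    return [
        f"{eo['ratio']:.2f} ({eo['ci_low']:.2f}-{eo['ci_high']:.2f})",
        f"{block['brier']:.3f}",
        f"{block['yates_slope']:.3f}",
        f"{c['value']:.2f} ({c['ci_low']:.2f}-{c['ci_high']:.2f})",
        f"{t['value']:.2f}",
        f"{t['sensitivity']:.0f}",
        f"{t['specificity']:.0f}",
        f"{t['correctly_classified']:.0f}",
    ]


def render_performance_table(run: dict) -> pd.DataFrame:
    """Overall performance table: one (original, adjusted) column pair per model."""
    data = {}
    for name in run["models"]:
        perf = run["performance"][name]
        data[(name, "original")] = _fmt_block(perf["original"])
        data[(name, "adjusted")] = _fmt_block(perf["adjusted"])
    table = pd.DataFrame(data, index=list(METRIC_ROWS))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["model", "version"])
    return table


_SUBGROUP_COLUMNS = (
    ("sex", "male"),
    ("sex", "female"),
    ("age_band", "<60"),
    ("age_band", ">=60"),
    ("bmi_band", "<25"),
    ("bmi_band", ">=25"),
)

_SUBGROUP_ROWS = ("E/O (95% CI)", "Brier score", "Yates slope", "C-statistic (95% CI)")


def render_subgroup_table(run: dict) -> pd.DataFrame:
    """Subgroup table: six columns (male/female, <60/>=60, <25/>=25 BMI)."""
    rows = []
    index = []
    for name in run["models"]:
        sub = run["performance"][name]["subgroups"]
        for metric_i, metric in enumerate(_SUBGROUP_ROWS):
            row = []
            for axis, level in _SUBGROUP_COLUMNS:
                block = sub[axis][level]
                row.append(_fmt_block(block)[metric_i] if block.get("defined") else UNDEFINED)
            rows.append(row)
            index.append((name, metric))
    cols = [f"{lvl} ({ax})" if ax != "sex" else lvl for ax, lvl in _SUBGROUP_COLUMNS]
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index), columns=cols)
    return table


def render_report(run: dict, fmt: str = "tsv") -> str:
    """Render the run as text: 'tsv' or 'md' (markdown)."""
    perf = render_performance_table(run)
    sub = render_subgroup_table(run)
    if fmt == "tsv":
        return perf.to_csv(sep="\t") + "\n" + sub.to_csv(sep="\t")
    if fmt == "md":
        return perf.to_markdown() + "\n\n" + sub.to_markdown()
    raise RiskvalInputError(f"unknown report format {fmt!r}; use 'tsv' or 'md'")


def save_run(run: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(run, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_run(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
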