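"""Recalibration-in-the-large via intercept adjustment.

The correction factor is the log odds ratio of the observed prevalence to
the mean predicted risk in the validation set,

    delta = ln[ prev / (1 - prev) ] - ln[ pbar / (1 - pbar) ],

added to every linear predictor.  It moves the mean predicted risk toward
the observed prevalence without touching the model's coefficients, so the
ranking of participants - and hence the C statistic - is unchanged.

Because the logistic function is nonlinear, a single adjustment does not
exactly equalise mean prediction and prevalence; the one-shot form is the
default, with an iterated variant available for convergence checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit

from .errors import DegenerateAnalysisError, SchemaError
from .metrics import _check_preds
from .models import ModelSpec, ScoreLink


@dataclass(frozen=True)
class InterceptAdjustment:
    """A fitted intercept correction.

    ``delta`` is added to every linear predictor; it is zero exactly when
    the mean predicted risk already equals the observed prevalence.
    """

    delta: float
    observed_prev: float
    mean_predicted: float


def fit_intercept_adjustment(p, y) -> InterceptAdjustment:
    """Fit the correction factor from a prediction set."""
    p, y = _check_preds(p, y)
    prev = float(y.mean())
    pbar = float(p.mean())
    if not (0.0 < prev < 1.0):
        raise DegenerateAnalysisError(
            f"intercept adjustment undefined at degenerate prevalence {prev}"
        )
    if not (0.0 < pbar < 1.0):
        raise DegenerateAnalysisError(
            f"intercept adjustment undefined at degenerate mean prediction {pbar}"
        )
    delta = math.log(prev / (1 - prev)) - math.log(pbar / (1 - pbar))
    return InterceptAdjustment(delta=delta, observed_prev=prev, mean_predicted=pbar)


def apply_intercept_adjustment(model: ModelSpec, adj: InterceptAdjustment) -> ModelSpec:
    """Return a new model with the correction folded into its intercept.

    Coefficients are untouched; predicted probabilities on any dataset are
    a strictly monotone image of the originals.
    """
    if model.link == "logistic":
        new = replace(model, intercept=model.intercept + adj.delta)
    elif model.link == "logistic_score":
        new = replace(
            model,
            score_link=ScoreLink(model.score_link.intercept + adj.delta, model.score_link.slope),
        )
    else:
        raise SchemaError(f"intercept adjustment requires a logistic link, got {model.link!r}")
    note = (
        f"intercept-adjusted from '{model.name}' with delta={adj.delta:.6f} "
        f"(observed prev {adj.observed_prev:.4f}, mean predicted {adj.mean_predicted:.4f})"
    )
    return replace(new, provenance=note)


def adjust_probabilities(p, delta: float) -> np.ndarray:
    """Apply a fitted correction directly to predicted probabilities."""
    p = np.asarray(p, dtype=float)
    return expit(logit(p) + delta)


def iterate_intercept_adjustment(
    p, y, tol: float = 1e-8, max_iter: int = 50
) -> tuple[float, int]:
    """Iterate fit+apply until mean prediction matches prevalence.

    Returns the total accumulated delta and the number of iterations used.
    Exists as a documented convergence check, not as the default analysis.
    """
    p, y = _check_preds(p, y)
    prev = float(y.mean())
    total = 0.0
    cur = p
    for i in range(1, max_iter + 1):
        adj = fit_intercept_adjustment(cur, y)
        total += adj.delta
        cur = adjust_probabilities(p, total)
        if abs(float(cur.mean()) - prev) < tol:
            return total, i
    raise DegenerateAnalysisError(
        f"intercept iteration did not reach |pbar - prev| < {tol} in {max_iter} steps"
    )
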