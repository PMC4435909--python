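"""Discrimination, calibration and threshold statistics.

All functions take a pair of aligned arrays: predicted probabilities ``p``
in [0, 1] and binary outcomes ``y`` in {0, 1}.

Conventions
-----------
* Classification rule: predict positive iff ``p >= threshold`` (boundary
  inclusive).
* The concordance statistic counts tied prediction pairs as half
  concordant; its confidence interval uses the nonparametric variance of
  the concordance estimator built from per-subject structural components
  (the same components drive the paired comparison test for two correlated
  C statistics).
* The E/O ratio confidence interval uses the Poisson log-scale
  approximation ``ratio * exp(+/- 1.96 / sqrt(O))``.
* Calibration curves use quantile (decile by default) bins of predicted
  risk; ties that straddle a bin edge are merged so each distinct value
  lives in one bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateAnalysisError, PairingError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _check_preds(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("p and y must be equal-length 1-d arrays with n >= 1")
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return p, y


def _require_both_classes(y: np.ndarray, what: str) -> None:
    if y.min() == y.max():
        raise DegenerateAnalysisError(
            f"{what} is undefined on a single-class outcome (all y = {int(y[0])})"
        )


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CStatistic:
    c: float
    ci_low: float
    ci_high: float
    se: float


def _structural_components(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-event and per-non-event placement components.

    ``v10[i]`` is the fraction of non-events scored below event i (ties
    half); ``v01[j]`` the fraction of events scored above non-event j.
    Both have mean equal to the concordance statistic.
    """
    pos = np.sort(p[y == 1])
    neg = np.sort(p[y == 0])
    pos_orig = p[y == 1]
    neg_orig = p[y == 0]
    n1, n0 = len(pos), len(neg)
    below = np.searchsorted(neg, pos_orig, side="left")
    ties = np.searchsorted(neg, pos_orig, side="right") - below
    v10 = (below + 0.5 * ties) / n0
    above = n1 - np.searchsorted(pos, neg_orig, side="right")
    ties0 = np.searchsorted(pos, neg_orig, side="right") - np.searchsorted(
        pos, neg_orig, side="left"
    )
    v01 = (above + 0.5 * ties0) / n1
    return v10, v01


def c_statistic(p, y) -> CStatistic:
    """Concordance (C) statistic with a 95% nonparametric CI.

    c = [#concordant + 0.5 * #tied] / #(event, non-event) pairs.
    """
    p, y = _check_preds(p, y)
    _require_both_classes(y, "the C statistic")
    v10, v01 = _structural_components(p, y)
    c = float(v10.mean())
    var = _component_variance(v10) + _component_variance(v01)
    se = float(np.sqrt(var))
    return CStatistic(
        c=c,
        ci_low=max(0.0, c - Z95 * se),
        ci_high=min(1.0, c + Z95 * se),
        se=se,
    )


def _component_variance(v: np.ndarray) -> float:
    if len(v) < 2:
        return 0.0
    return float(np.var(v, ddof=1) / len(v))


@dataclass(frozen=True)
class CComparison:
    delta: float
    p_value: float
    se: float
    c_a: float
    c_b: float


def compare_c_statistics(p_a, y_a, p_b, y_b) -> CComparison:
    """Paired nonparametric comparison of two correlated C statistics.

    Both prediction sets must cover the identical subjects in the same
    order.  The test statistic is the difference of the two concordance
    estimates over its nonparametric standard error computed from the
    paired structural components; swapping the inputs negates the delta
    and leaves the p-value unchanged.
    """
    p_a, y_a = _check_preds(p_a, y_a)
    p_b, y_b = _check_preds(p_b, y_b)
    if len(y_a) != len(y_b) or not np.array_equal(y_a, y_b):
        raise PairingError("paired comparison requires identical subjects and outcomes")
    _require_both_classes(y_a, "the C-statistic comparison")
    v10a, v01a = _structural_components(p_a, y_a)
    v10b, v01b = _structural_components(p_b, y_b)
    c_a = float(v10a.mean())
    c_b = float(v10b.mean())
    delta = c_a - c_b
    var = _component_variance(v10a - v10b) + _component_variance(v01a - v01b)
    se = float(np.sqrt(var))
    if se == 0.0:
        p_value = 1.0 if delta == 0.0 else 0.0
    else:
        z = delta / se
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    return CComparison(delta=delta, p_value=p_value, se=se, c_a=c_a, c_b=c_b)


def bootstrap_compare_c(p_a, y, p_b, n_boot: int = 2000, seed: int = 0) -> float:
    """Paired-bootstrap p-value for the C difference (cross-check variant).

    Resamples subjects with replacement, recomputes both C statistics per
    replicate and returns ``2 * min(P(delta* <= 0), P(delta* >= 0))``.
    Replicates that lose one outcome class are dropped.
    """
    p_a, y = _check_preds(p_a, y)
    p_b, _ = _check_preds(p_b, y)
    _require_both_classes(y, "the bootstrap C comparison")
    rng = np.random.default_rng(seed)
    n = len(y)
    deltas = np.empty(n_boot)
    kept = 0
    chunk = max(1, min(n_boot, int(2e7 // max(n, 1))))
    while kept < n_boot:
        m = min(chunk, n_boot - kept)
        idx = rng.integers(0, n, size=(m, n))
        yb = y[idx]
        valid = (yb.sum(axis=1) > 0) & (yb.sum(axis=1) < n)
        if not valid.any():
            continue
        idx = idx[valid]
        yb = yb[valid]
        da = _auc_rows(p_a[idx], yb) - _auc_rows(p_b[idx], yb)
        take = min(len(da), n_boot - kept)
        deltas[kept : kept + take] = da[:take]
        kept += take
    lo = float(np.mean(deltas <= 0))
    hi = float(np.mean(deltas >= 0))
    return min(1.0, 2.0 * min(lo, hi))


def _auc_rows(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise AUC via midranks (p, y are 2-d with one replicate per row)."""
    ranks = stats.rankdata(p, axis=1)
    n1 = y.sum(axis=1)
    n0 = y.shape[1] - n1
    rank_sum = (ranks * y).sum(axis=1)
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def brier_score(p, y) -> float:
    """Mean squared difference between prediction and outcome; 0 is perfect."""
    p, y = _check_preds(p, y)
    return float(np.mean((p - y) ** 2))


def yates_slope(p, y) -> float:
    """Mean predicted probability in events minus non-events; higher is better."""
    p, y = _check_preds(p, y)
    _require_both_classes(y, "the Yates slope")
    return float(p[y == 1].mean() - p[y == 0].mean())


@dataclass(frozen=True)
class EORatio:
    e: float
    o: int
    ratio: float
    ci_low: float
    ci_high: float


def eo_ratio(p, y) -> EORatio:
    """Expected/observed event ratio with a Poisson log-scale 95% CI."""
    p, y = _check_preds(p, y)
    e = float(p.sum())
    o = int(y.sum())
    if o == 0:
        raise DegenerateAnalysisError(f"E/O undefined with zero observed events (E = {e:.3f})")
    ratio = e / o
    half = Z95 / np.sqrt(o)
    return EORatio(e=e, o=o, ratio=ratio, ci_low=ratio * np.exp(-half),
                   ci_high=ratio * np.exp(half))


@dataclass(frozen=True)
class Miscalibration:
    direction: str  # 'over' (ratio >= 1) or 'under'
    percent: float
    ci_low: float
    ci_high: float


def miscalibration_percent(r: EORatio) -> Miscalibration:
    """Express an E/O ratio as a signed over/underestimation percentage.

    Over: (ratio - 1) * 100 with CI endpoints mapped the same way.
    Under: (1 - ratio) * 100, with the CI endpoints swapped so the
    reported interval stays (low, high).
    """
    if r.ratio >= 1.0:
        return Miscalibration(
            "over",
            (r.ratio - 1.0) * 100.0,
            (r.ci_low - 1.0) * 100.0,
            (r.ci_high - 1.0) * 100.0,
        )
    return Miscalibration(
        "under",
        (1.0 - r.ratio) * 100.0,
        (1.0 - r.ci_high) * 100.0,
        (1.0 - r.ci_low) * 100.0,
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Binned predicted vs observed rates, plus the rug of predictions."""

    mean_predicted: tuple[float, ...]
    observed_rate: tuple[float, ...]
    counts: tuple[int, ...]
    rug: tuple[float, ...]
    binning: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, len(self.counts) + 1),
                "mean_pred": self.mean_predicted,
                "obs_rate": self.observed_rate,
                "count": self.counts,
            }
        )


def calibration_curve(p, y, n_bins: int = 10) -> CalibrationCurve:
    """Quantile-binned calibration curve (deciles of predicted risk by default)."""
    p, y = _check_preds(p, y)
    if len(p) < n_bins:
        raise DegenerateAnalysisError(
            f"cannot form {n_bins} quantile bins from {len(p)} predictions; lower n_bins"
        )
    if p.min() == p.max():
        # constant predictions occupy a single bin
        return CalibrationCurve(
            mean_predicted=(float(p[0]),),
            observed_rate=(float(y.mean()),),
            counts=(len(p),),
            rug=tuple(float(v) for v in np.sort(p)),
            binning=f"quantile bins (requested {n_bins}, realised 1; constant input)",
        )
    binned = pd.qcut(p, n_bins, duplicates="drop")
    frame = pd.DataFrame({"p": p, "y": y, "bin": binned})
    grouped = frame.groupby("bin", observed=True, sort=True)
    agg = grouped.agg(mean_pred=("p", "mean"), obs_rate=("y", "mean"), count=("p", "size"))
    return CalibrationCurve(
        mean_predicted=tuple(float(v) for v in agg["mean_pred"]),
        observed_rate=tuple(float(v) for v in agg["obs_rate"]),
        counts=tuple(int(v) for v in agg["count"]),
        rug=tuple(float(v) for v in np.sort(p)),
        binning=f"quantile bins (requested {n_bins}, realised {len(agg)})",
    )


# ---------------------------------------------------------------------------
# Threshold analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPerformance:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    correctly_classified: float  # percent
    youden_j: float


def classification_at(p, y, threshold: float) -> ThresholdPerformance:
    """Sensitivity/specificity/accuracy at one threshold (positive iff p >= t)."""
    p, y = _check_preds(p, y)
    pred = p >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fn = float(np.sum(~pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))
    fp = float(np.sum(pred & (y == 0)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = 100.0 * (tp + tn) / len(y)
    j = sens / 100.0 + spec / 100.0 - 1.0
    return ThresholdPerformance(float(threshold), sens, spec, acc, j)


def optimal_threshold(p, y) -> ThresholdPerformance:
    """Youden-optimal operating point over the distinct predicted values.

    Scans every distinct prediction as a candidate threshold and returns
    the one maximising J = sensitivity + specificity - 1; ties in J are
    broken in favour of the lower threshold (higher sensitivity).
    """
    p, y = _check_preds(p, y)
    _require_both_classes(y, "the optimal threshold")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ys = y[order]
    n1 = ys.sum()
    n0 = len(ys) - n1
    # At threshold t = distinct value v: positives are p >= v.
    distinct, first_idx = np.unique(ps, return_index=True)
    cum_pos_below = np.concatenate(([0.0], np.cumsum(ys)))  # events strictly below index i
    tp = n1 - cum_pos_below[first_idx]
    fp = n0 - (first_idx - cum_pos_below[first_idx])
    sens = tp / n1
    spec = 1.0 - fp / n0
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest threshold) tie
    t = float(distinct[best])
    return classification_at(p, y, t)
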