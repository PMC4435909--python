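"""Discrimination, calibration and threshold statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from riskval.errors import DegenerateAnalysisError, PairingError
from riskval.metrics import (
    EORatio,
    bootstrap_compare_c,
    brier_score,
    c_statistic,
    calibration_curve,
    classification_at,
    compare_c_statistics,
    eo_ratio,
    miscalibration_percent,
    optimal_threshold,
    yates_slope,
)

from conftest import make_preds


def c_brute_force(p, y):
    """O(n^2) pairwise enumeration oracle for the concordance statistic."""
    pos = p[y == 1][:, None]
    neg = p[y == 0][None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size / 1))


# --- C statistic -----------------------------------------------------------

def test_c_statistic_examples():
    assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).c == 1.0
    assert c_statistic([0.4] * 6, [1, 0, 1, 0, 0, 0]).c == 0.5
    res = c_statistic([0.9, 0.8, 0.1, 0.3], [1, 0, 0, 1])
    assert res.c == pytest.approx(0.75)
    assert res.ci_low <= res.c <= res.ci_high


def test_c_statistic_degenerate_inputs():
    with pytest.raises(DegenerateAnalysisError):
        c_statistic([0.2, 0.4], [1, 1])
    with pytest.raises(ValueError):
        c_statistic([0.2, 1.4], [1, 0])


@pytest.mark.parametrize("seed", range(40))
def test_c_statistic_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 150))
    p, y = make_preds(seed + 1000, n=n, ties=bool(seed % 2))
    assert c_statistic(p, y).c == pytest.approx(c_brute_force(p, y), abs=1e-12)


def test_c_statistic_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    for seed in range(10):
        p, y = make_preds(seed, n=300, ties=bool(seed % 2))
        assert c_statistic(p, y).c == pytest.approx(roc_auc_score(y, p), abs=1e-12)


@given(st.integers(0, 50), st.sampled_from(["exp", "cube", "affine"]))
def test_c_invariant_under_monotone_transform(seed, kind):
    p, y = make_preds(seed, n=80, ties=True)
    if kind == "exp":
        q = 1 - np.exp(-3 * p)
    elif kind == "cube":
        q = p**3
    else:
        q = 0.2 + 0.5 * p
    assert c_statistic(np.clip(q, 0, 1), y).c == pytest.approx(c_statistic(p, y).c, abs=1e-12)


# --- paired C comparison ---------------------------------------------------

def test_compare_with_self_and_symmetry():
    p, y = make_preds(3, n=150)
    q, _ = make_preds(4, n=150)
    q = np.clip(0.7 * p + 0.3 * q, 0, 1)
    same = compare_c_statistics(p, y, p, y)
    assert same.delta == 0.0 and same.p_value == 1.0
    ab = compare_c_statistics(p, y, q, y)
    ba = compare_c_statistics(q, y, p, y)
    assert ab.delta == pytest.approx(-ba.delta)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_compare_rejects_mismatched_subjects():
    p, y = make_preds(5, n=50)
    y2 = y.copy()
    y2[0] = 1 - y2[0]
    with pytest.raises(PairingError):
        compare_c_statistics(p, y, p, y2)


def test_compare_agrees_with_paired_bootstrap():
    """Small paired set: analytic p within 0.02 of a 1e5-replicate bootstrap."""
    from scipy.special import expit

    rng = np.random.default_rng(42)
    n = 20
    y = np.array([1] * 8 + [0] * 12, dtype=float)
    latent = rng.standard_normal(n) + y
    p_a = expit(latent + 0.3 * rng.standard_normal(n))
    p_b = expit(0.6 * latent + 0.8 * rng.standard_normal(n))
    analytic = compare_c_statistics(p_a, y, p_b, y).p_value
    boot = bootstrap_compare_c(p_a, y, p_b, n_boot=100_000, seed=7)
    assert abs(analytic - boot) <= 0.02


# --- calibration summaries -------------------------------------------------

def test_brier_examples():
    y = np.array([1, 0, 0, 1.0])
    assert brier_score(y, y) == 0.0
    assert brier_score([0.5] * 4, y) == pytest.approx(0.25)
    assert brier_score([0.8, 0.2, 0.6], [1, 0, 0]) == pytest.approx(0.44 / 3)


def test_brier_closed_form_at_constant_prevalence():
    _, y = make_preds(9, n=400)
    prev = y.mean()
    assert brier_score(np.full_like(y, prev), y) == pytest.approx(prev * (1 - prev))


def test_yates_slope_examples():
    y = np.array([1, 0, 1, 0.0])
    assert yates_slope(y, y) == 1.0
    assert yates_slope([0.3] * 4, y) == 0.0
    assert yates_slope([0.8, 0.2, 0.6], [1, 0, 0]) == pytest.approx(0.4)
    with pytest.raises(DegenerateAnalysisError):
        yates_slope([0.5, 0.6], [1, 1])


def test_eo_ratio_and_ci():
    _, y = make_preds(11, n=500)
    assert eo_ratio(np.full_like(y, y.mean()), y).ratio == pytest.approx(1.0)
    r = eo_ratio([0.9, 0.6], [1, 0])
    assert r.ratio == pytest.approx(1.5)
    # o = 100 at ratio 1: CI = exp(+/- 1.96/10)
    p100 = np.concatenate([np.full(100, 1.0), np.zeros(100)])
    y100 = p100.copy()
    r100 = eo_ratio(p100, y100)
    assert r100.ratio == 1.0
    assert r100.ci_low == pytest.approx(np.exp(-1.959963984540054 / 10), abs=1e-4)
    assert r100.ci_high == pytest.approx(np.exp(1.959963984540054 / 10), abs=1e-4)
    with pytest.raises(DegenerateAnalysisError):
        eo_ratio([0.2, 0.3], [0, 0])


def test_miscalibration_published_identities():
    over = miscalibration_percent(EORatio(e=0, o=0, ratio=1.81, ci_low=1.09, ci_high=2.52))
    assert over.direction == "over"
    assert (round(over.percent), round(over.ci_low), round(over.ci_high)) == (81, 9, 152)
    under = miscalibration_percent(EORatio(e=0, o=0, ratio=0.26, ci_low=0.13, ci_high=0.39))
    assert under.direction == "under"
    assert (round(under.percent), round(under.ci_low), round(under.ci_high)) == (74, 61, 87)
    exact = miscalibration_percent(EORatio(e=1, o=1, ratio=1.0, ci_low=0.9, ci_high=1.1))
    assert exact.percent == 0.0


def test_calibration_curve_properties():
    rng = np.random.default_rng(12)
    p = rng.beta(2, 5, size=5000)
    y = (rng.random(5000) < p).astype(float)  # perfectly calibrated by design
    curve = calibration_curve(p, y, n_bins=10)
    assert sum(curve.counts) == 5000
    assert list(curve.mean_predicted) == sorted(curve.mean_predicted)
    for mp, orate, cnt in zip(curve.mean_predicted, curve.observed_rate, curve.counts):
        se = np.sqrt(mp * (1 - mp) / cnt)
        assert abs(orate - mp) < 4 * se + 1e-9

    const = calibration_curve(np.full(50, 0.3), (np.arange(50) < 15).astype(float))
    assert len(const.counts) == 1 and const.mean_predicted[0] == pytest.approx(0.3)

    distinct = calibration_curve(np.linspace(0.01, 0.99, 100), np.zeros(100) + (np.arange(100) % 2))
    assert list(distinct.counts) == [10] * 10

    with pytest.raises(DegenerateAnalysisError):
        calibration_curve([0.1, 0.2], [0, 1], n_bins=10)


# --- thresholds ------------------------------------------------------------

def test_optimal_threshold_examples():
    sep = optimal_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert sep.youden_j == pytest.approx(1.0)
    assert sep.sensitivity == 100.0 and sep.specificity == 100.0

    const = optimal_threshold([0.4] * 6, [1, 0, 1, 0, 0, 0])
    assert const.youden_j == pytest.approx(0.0)

    res = optimal_threshold([0.9, 0.6, 0.7, 0.2, 0.1], [1, 1, 0, 0, 0])
    assert res.threshold == pytest.approx(0.6)
    assert res.sensitivity == pytest.approx(100.0)
    assert res.specificity == pytest.approx(200 / 3)
    assert res.youden_j == pytest.approx(2 / 3)


@pytest.mark.parametrize("seed", range(30))
def test_optimal_threshold_matches_grid_oracle(seed):
    """J equals the max over an exhaustive grid including all midpoints."""
    p, y = make_preds(seed + 50, n=int(np.random.default_rng(seed).integers(5, 80)),
                      ties=bool(seed % 3))
    res = optimal_threshold(p, y)
    vals = np.unique(p)
    grid = np.concatenate([[0.0], vals, (vals[:-1] + vals[1:]) / 2, [1.0 + 1e-9]])
    best = max(classification_at(p, y, t).youden_j for t in grid)
    assert res.youden_j == pytest.approx(best, abs=1e-12)


def test_classification_published_identities():
    """Accuracy identity reproduces the published 50% and 64% cells."""
    prev = 0.176
    omani = 85 * prev + 42 * (1 - prev)
    rotterdam = 57 * prev + 65 * (1 - prev)
    assert round(omani) == 50
    assert round(rotterdam) == 64


def test_classification_at_edges_and_identity():
    p, y = make_preds(21, n=250)
    zero = classification_at(p, y, 0.0)
    assert zero.sensitivity == 100.0 and zero.specificity == 0.0
    prev = y.mean()
    for t in (0.2, 0.5, 0.8):
        r = classification_at(p, y, t)
        assert r.correctly_classified == pytest.approx(
            r.sensitivity * prev + r.specificity * (1 - prev)
        )
        assert r.youden_j == pytest.approx(r.sensitivity / 100 + r.specificity / 100 - 1)
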