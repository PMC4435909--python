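"""Multiple imputation by chained equations, and pooled validation.

Implements the minimal standard machinery needed for a complete-case
sensitivity analysis: each variable with missing values gets a conditional
model on all other analysis variables (normal linear model with
approximate-posterior parameter draws for continuous variables, logistic
model draws for binaries), cycled a fixed number of times; the procedure
is repeated m times from independent sub-seeds to give m completed
datasets.  Originally observed cells are never altered.

Pooling follows the point-similarity question asked of the sensitivity
analysis: the per-dataset concordance statistics are reported together
with their mean (and min-max spread); no Rubin's-rules variance pooling
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .metrics import c_statistic
from .models import ModelSpec, score_cohort

#: Default number of completed datasets and chained-equation cycles.
DEFAULT_M = 5
DEFAULT_CYCLES = 10

#: Variables eligible to appear in conditional imputation models, with
#: their type.  The outcome measurements are included as predictors of
#: missing covariates (and are themselves imputable).
_CONTINUOUS = ("age", "height", "weight", "bmi", "waist", "sbp", "dbp",
               "fpg", "glucose_2h", "hdl", "triglycerides")
_BINARY = ("on_htn_meds", "smoker", "corticosteroids",
           "fh_mother", "fh_father", "fh_sister", "fh_brother",
           "alcohol_ever", "alcohol_current")


@dataclass(frozen=True)
class ImputedSet:
    """m completed datasets plus the provenance needed to reproduce them."""

    datasets: tuple[pd.DataFrame, ...]
    rng_seed: int
    m: int
    cycles: int
    imputed_variables: tuple[str, ...]
    #: rows whose outcome classification rests on at least one imputed
    #: glucose value (they are retained downstream, flagged here)
    n_outcome_imputed: int = 0


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    x = df[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), x])


def _draw_mvn(mean: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    """Draw from N(mean, cov) via an eigenvalue-clipped factor (the fitted
    covariance can be numerically asymmetric/indefinite)."""
    sym = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    return mean + (v * np.sqrt(w)) @ rng.standard_normal(len(mean))


def _draw_linear(x_obs, y_obs, x_mis, rng):
    """Bayesian-flavoured normal-model draw for continuous imputations."""
    n, k = x_obs.shape
    beta_hat, *_ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    resid = y_obs - x_obs @ beta_hat
    dof = max(n - k, 2)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    xtx = x_obs.T @ x_obs + 1e-8 * np.eye(k)
    cov = sigma2 * np.linalg.inv(xtx)
    beta = _draw_mvn(beta_hat, cov, rng)
    return x_mis @ beta + rng.standard_normal(len(x_mis)) * np.sqrt(sigma2)


def _draw_logistic(x_obs, y_obs, x_mis, rng):
    """Logistic-model draw for binary imputations.

    Falls back to a marginal Bernoulli draw if the fit is degenerate
    (perfect separation, single observed class).
    """
    p_marg = float(y_obs.mean())
    if p_marg in (0.0, 1.0):
        return np.full(len(x_mis), p_marg)
    try:
        import statsmodels.api as sm

        with np.errstate(all="ignore"):
            fit = sm.GLM(y_obs, x_obs, family=sm.families.Binomial()).fit(maxiter=50)
            beta_hat = np.asarray(fit.params)
            cov = np.asarray(fit.cov_params())
            if not np.all(np.isfinite(beta_hat)) or not np.all(np.isfinite(cov)):
                raise ValueError("non-finite logistic fit")
            beta = _draw_mvn(beta_hat, cov, rng)
            eta = np.clip(x_mis @ beta, -30, 30)
            prob = 1.0 / (1.0 + np.exp(-eta))
    except Exception:
        prob = np.full(len(x_mis), p_marg)
    return (rng.random(len(x_mis)) < prob).astype(float)


def impute_chained(
    cohort: pd.DataFrame,
    required_vars: list[str] | None = None,
    m: int = DEFAULT_M,
    seed: int = 0,
    cycles: int = DEFAULT_CYCLES,
) -> ImputedSet:
    """Chained-equations multiple imputation.

    Parameters
    ----------
    cohort
        Roster with missing values (raw columns; derived variables are
        recomputed downstream).
    required_vars
        Raw columns that must be complete afterwards; defaults to every
        analysis variable present in the cohort.  Each must have at least
        one observed value.
    m, cycles, seed
        Number of completed datasets, chained-equation cycles per dataset,
        and the master seed (sub-seeds are spawned deterministically).
    """
    candidates = [c for c in (*_CONTINUOUS, *_BINARY) if c in cohort.columns]
    targets = list(required_vars) if required_vars is not None else candidates
    targets = [c for c in targets if c in candidates]
    for var in targets:
        if cohort[var].notna().sum() == 0:
            raise ConfigError(f"variable {var!r} is fully missing and cannot be imputed")
    to_impute = [c for c in targets if cohort[c].isna().any()]
    predictors = [c for c in candidates if cohort[c].notna().all() or c in to_impute]

    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(m)
    datasets = []
    for child in child_seeds:
        rng = np.random.default_rng(child)
        work = cohort.copy()
        # Initial fill: draw from the observed empirical distribution.
        for var in to_impute:
            obs = work[var].dropna().to_numpy(dtype=float)
            miss = work[var].isna()
            work.loc[miss, var] = rng.choice(obs, size=int(miss.sum()), replace=True)
        if to_impute:
            female = (cohort["sex"] == "female").astype(float).to_numpy() \
                if "sex" in cohort.columns else np.zeros(len(cohort))
            for _ in range(cycles):
                for var in to_impute:
                    miss = cohort[var].isna().to_numpy()
                    other = [c for c in predictors if c != var]
                    x = np.column_stack(
                        [np.ones(len(work)), female, work[other].to_numpy(dtype=float)]
                    )
                    y_all = work[var].to_numpy(dtype=float)
                    if var in _BINARY:
                        drawn = _draw_logistic(x[~miss], y_all[~miss], x[miss], rng)
                    else:
                        drawn = _draw_linear(x[~miss], y_all[~miss], x[miss], rng)
                    work.loc[miss, var] = drawn
        datasets.append(work)
    glu = [v for v in ("fpg", "glucose_2h") if v in to_impute]
    n_outcome_imputed = (
        int(cohort[glu].isna().any(axis=1).sum()) if glu else 0
    )
    return ImputedSet(
        datasets=tuple(datasets),
        rng_seed=seed,
        m=m,
        cycles=cycles,
        imputed_variables=tuple(to_impute),
        n_outcome_imputed=n_outcome_imputed,
    )


@dataclass(frozen=True)
class PooledValidation:
    """Per-dataset and pooled discrimination for one model."""

    per_dataset_c: tuple[float, ...]
    pooled_c: float
    c_min: float
    c_max: float
    n_with_imputed_outcome: int


def pooled_validation(imputed: ImputedSet, model: ModelSpec) -> PooledValidation:
    """Concordance statistic per completed dataset plus their mean.

    Each completed dataset is classified with the WHO glucose rule (so
    records whose outcome rested on imputed glucose are retained, and
    counted in ``n_with_imputed_outcome``) and scored with the model.
    """
    from .cohort import add_derived_variables, outcome_series

    cs = []
    for ds in imputed.datasets:
        full = add_derived_variables(ds)
        y = outcome_series(full)
        keep = y.notna()
        if "prior_diagnosis" in full.columns:
            keep &= full["prior_diagnosis"] != 1
        sub = full.loc[keep]
        p = score_cohort(model, sub)
        cs.append(c_statistic(p, y.loc[keep].to_numpy()).c)
    cs_arr = np.asarray(cs, dtype=float)
    return PooledValidation(
        per_dataset_c=tuple(cs),
        pooled_c=float(cs_arr.mean()),
        c_min=float(cs_arr.min()),
        c_max=float(cs_arr.max()),
        n_with_imputed_outcome=imputed.n_outcome_imputed,
    )
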