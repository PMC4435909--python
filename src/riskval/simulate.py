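"""Synthetic cohort generator.

Generates participant rosters with the statistical structure of an urban
South African community screening sample: ~79% female, per-sex covariate
means/SDs matching the published cohort profile, a ~17.6% screen-detected
diabetes prevalence defined through the WHO OGTT rule, a 173/1256 prior-
diagnosis fraction, and a missing-data pattern that removes roughly
346/1083 of the undiagnosed at the eligibility stage.

Construction, in order:

1. Sex ~ Bernoulli(female_frac).
2. Continuous covariates (age, BMI, waist, SBP, DBP, height, weight, HDL,
   triglycerides) through a Gaussian copula with per-sex marginals:
   moment-matched truncated normals for bounded variables, a
   moment-matched lognormal for triglycerides.  The rank-correlation
   structure is a documented default, not derived from the published
   cohort (which prints marginals only).
3. Binary covariates per-sex: antihypertensive medication is linked to the
   SBP copula score (probit loading) so treatment tracks pressure; the
   four family-history indicators share a per-participant frailty factor;
   the rest are independent Bernoulli draws.
4. A latent risk score on the copula scores of age, BMI and waist, the
   family-history count and sex selects membership of an "elevated
   glycaemia" component.  Fasting glucose is a two-component per-sex
   mixture (base truncated-normal component + elevated lognormal tail);
   the base component's moments are solved from the realised tail
   fraction so the marginal FPG mean/SD equal the configured values.
   2-h glucose is component-conditional, correlated with the FPG deviate,
   and is calibrated only through the prevalence target.
5. The outcome is *not* drawn as a Bernoulli label: it emerges from the
   WHO glucose rule applied to the generated measurements, so the
   classification path is exercised end to end.

``calibrate_outcome_intercept`` bisects the latent-model intercept on a
large fixed-seed sample until the empirical screen-detected prevalence
hits the target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .cohort import outcome_series
from .errors import CalibrationError, ConfigError

#: Fixed seed for the calibration sample (kept independent of user seeds so
#: a given configuration always calibrates to the same intercept).
CALIBRATION_SEED = 20080115

_COPULA_VARS = ("age", "bmi", "waist", "sbp", "dbp", "height", "weight", "hdl", "triglycerides")
_FH_VARS = ("fh_mother", "fh_father", "fh_sister", "fh_brother")


def _default_continuous() -> dict:
    # (mean, sd) per sex; published per-sex cohort profile.  'fpg' is a
    # marginal target for the mixture model, not a copula variable.
    return {
        "fpg": {"male": (5.4, 1.4), "female": (5.7, 2.0)},
        "age": {"male": (53.5, 15.0), "female": (52.1, 14.3)},
        "bmi": {"male": (25.5, 5.8), "female": (29.6, 7.0)},
        "waist": {"male": (92.5, 15.2), "female": (95.6, 14.7)},
        "sbp": {"male": (124.3, 16.6), "female": (121.6, 19.2)},
        "dbp": {"male": (75.6, 11.1), "female": (74.7, 12.1)},
        "height": {"male": (1.7, 0.1), "female": (1.6, 0.1)},
        "weight": {"male": (72.3, 16.4), "female": (73.9, 17.7)},
        "hdl": {"male": (1.2, 0.4), "female": (1.3, 0.3)},
        "triglycerides": {"male": (1.4, 0.9), "female": (1.4, 0.9)},
    }


def _default_bounds() -> dict:
    return {
        "age": (15.0, 95.0),
        "bmi": (13.0, 65.0),
        "waist": (45.0, 170.0),
        "sbp": (70.0, 250.0),
        "dbp": (35.0, 140.0),
        "height": (1.30, 2.05),
        "weight": (30.0, 185.0),
        "hdl": (0.3, 3.5),
        "triglycerides": None,  # lognormal marginal
    }


def _default_binary() -> dict:
    return {
        "on_htn_meds": {"male": 0.274, "female": 0.359},
        "smoker": {"male": 0.561, "female": 0.405},
        "corticosteroids": {"male": 0.006, "female": 0.007},
        "alcohol_ever": {"male": 0.739, "female": 0.414},
        "alcohol_current": {"male": 0.510, "female": 0.219},
        "fh_mother": {"male": 0.108, "female": 0.159},
        "fh_father": {"male": 0.089, "female": 0.076},
        "fh_sister": {"male": 0.076, "female": 0.138},
        "fh_brother": {"male": 0.057, "female": 0.085},
    }


def _default_correlations() -> tuple:
    # Documented defaults; NOT derived from the published cohort, which
    # prints marginal summaries only.
    return (
        ("bmi", "waist", 0.80),
        ("sbp", "dbp", 0.70),
        ("age", "sbp", 0.35),
        ("age", "dbp", 0.20),
        ("bmi", "weight", 0.85),
        ("waist", "weight", 0.70),
        ("height", "weight", 0.45),
        ("bmi", "height", -0.10),
        ("age", "bmi", 0.10),
        ("age", "waist", 0.15),
        ("hdl", "bmi", -0.20),
        ("hdl", "waist", -0.20),
        ("hdl", "triglycerides", -0.30),
        ("triglycerides", "bmi", 0.20),
        ("triglycerides", "waist", 0.20),
    )


def _default_risk() -> dict:
    # Latent-risk loadings on copula z-scores / counts; 'intercept' is the
    # calibration handle (default value produced by
    # calibrate_outcome_intercept on the default configuration).
    return {
        "age": 0.55,
        "bmi": 0.45,
        "waist": 0.25,
        "fh_count": 0.35,
        "female": 0.30,
        "intercept": -1.9132505741801755,
    }


def _default_glucose() -> dict:
    return {
        # Elevated-component FPG (mean, sd), per sex, lognormal.
        "tail_fpg": {"male": (7.6, 2.0), "female": (8.3, 2.89)},
        # Base 2-h glucose lognormal (mean, sd); elevated 2-h normal (mean, sd).
        "base_g2h": (5.5, 1.5),
        "tail_g2h": (12.8, 3.0),
        # Correlation between the FPG deviate and the 2-h deviate.
        "rho_fpg_g2h": 0.5,
        # Floor for the solved base-component FPG variance.
        "min_base_var": 0.09,
    }


def _default_missing_rates() -> dict:
    # Chosen so 1 - prod(1 - r) over outcome/required fields is close to
    # the published stage-2 exclusion fraction 346/1083.
    return {
        "family_history": 0.21,  # block: all four relatives missing together
        "glucose_2h": 0.10,
        "waist": 0.03,
        "smoker": 0.015,
        "weight": 0.01,
        "fpg": 0.01,
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the published cohort profile."""

    n_total: int = 1256
    frac_prior_diagnosis: float = 173 / 1256
    frac_missing_excluded: float = 346 / 1083  # informational target
    female_frac: float = 0.787
    target_prevalence: float = 0.176
    continuous: dict = field(default_factory=_default_continuous)
    bounds: dict = field(default_factory=_default_bounds)
    binary: dict = field(default_factory=_default_binary)
    correlations: tuple = field(default_factory=_default_correlations)
    fh_frailty_loading: float = 0.5
    htn_bp_loading: float = 0.4
    risk: dict = field(default_factory=_default_risk)
    glucose: dict = field(default_factory=_default_glucose)
    missing_rates: dict = field(default_factory=_default_missing_rates)
    missing_mechanism: str = "MCAR"
    mar_driver: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("frac_prior_diagnosis", self.frac_prior_diagnosis),
            ("female_frac", self.female_frac),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError("target_prevalence must be in (0, 1)")
        for var, per_sex in self.continuous.items():
            for sex, (m, s) in per_sex.items():
                if s <= 0:
                    raise ConfigError(f"SD for {var}/{sex} must be positive")
        for var, per_sex in self.binary.items():
            for sex, prob in per_sex.items():
                if not 0.0 <= prob <= 1.0:
                    raise ConfigError(f"prevalence for {var}/{sex} must be in [0, 1]")
        _ = self.correlation_matrix()  # validates names and PSD-repairability

    def continuous_fpg(self, sex: str) -> tuple[float, float]:
        """Marginal (mean, sd) target for fasting plasma glucose."""
        return self.continuous["fpg"][sex]

    def correlation_matrix(self) -> np.ndarray:
        k = len(_COPULA_VARS)
        idx = {v: i for i, v in enumerate(_COPULA_VARS)}
        r = np.eye(k)
        for a, b, rho in self.correlations:
            if a not in idx or b not in idx:
                raise ConfigError(f"correlation names {a!r}/{b!r} not copula variables")
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"correlation {a}-{b} out of (-1, 1): {rho}")
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
        # Repair to the nearest PSD matrix by eigenvalue clipping.
        w, v = np.linalg.eigh(r)
        if w.min() < 1e-8:
            w = np.clip(w, 1e-8, None)
            r = v @ np.diag(w) @ v.T
            d = np.sqrt(np.diag(r))
            r = r / np.outer(d, d)
        return r


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


# ---------------------------------------------------------------------------
# Marginal transforms
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """(mu, sigma) whose (lo, hi)-truncated normal has the target moments."""
    if (mean - lo) / sd > 6.0 and (hi - mean) / sd > 6.0:
        return mean, sd

    def residual(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], tol=1e-12)
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-6:
        raise ConfigError(f"could not moment-match truncated normal ({mean}, {sd}) on [{lo}, {hi}]")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm_from_z(z: np.ndarray, mean: float, sd: float, bounds) -> np.ndarray:
    if bounds is None:
        return mean + sd * z
    lo, hi = bounds
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    fa = stats.norm.cdf((lo - mu) / sigma)
    fb = stats.norm.cdf((hi - mu) / sigma)
    u = stats.norm.cdf(z)
    return mu + sigma * stats.norm.ppf(fa + u * (fb - fa))


def _lognormal_from_z(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(mu + np.sqrt(s2) * z)


def _feasible_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Moment-matched truncated normal with a feasibility backoff.

    The base glycaemia component must live strictly below the fasting
    diagnostic threshold; when the requested (mean, sd) pair is not
    achievable on (lo, hi) the SD target is shrunk geometrically (the
    compromise only occurs far from the calibrated operating point).
    """
    mean = float(np.clip(mean, lo + 0.1, hi - 0.05))
    target_sd = sd
    for _ in range(12):
        try:
            mu, sigma = _truncnorm_params(mean, target_sd, lo, hi)
            return mean, target_sd, mu, sigma
        except ConfigError:
            target_sd *= 0.8
    raise ConfigError(f"no truncated normal on [{lo}, {hi}] near mean {mean}")


# ---------------------------------------------------------------------------
# Latent state and glucose
# ---------------------------------------------------------------------------

def _draw_latents(config: SimConfig, n: int, rng: np.random.Generator) -> dict:
    state: dict = {"n": n}
    female = rng.random(n) < config.female_frac
    state["female"] = female
    sex_key = np.where(female, "female", "male")

    chol = np.linalg.cholesky(config.correlation_matrix())
    z = rng.standard_normal((n, len(_COPULA_VARS))) @ chol.T
    state["z"] = {v: z[:, i] for i, v in enumerate(_COPULA_VARS)}

    x: dict = {}
    for var in _COPULA_VARS:
        vals = np.empty(n)
        for sex, mask in (("male", ~female), ("female", female)):
            if not mask.any():
                continue
            mean, sd = config.continuous[var][sex]
            bounds = config.bounds[var]
            if var == "triglycerides" or bounds is None:
                vals[mask] = _lognormal_from_z(state["z"][var][mask], mean, sd)
            else:
                vals[mask] = _truncnorm_from_z(state["z"][var][mask], mean, sd, bounds)
        x[var] = vals
    state["x"] = x

    def _per_sex_threshold(var: str) -> np.ndarray:
        return np.where(
            female,
            stats.norm.ppf(config.binary[var]["female"]),
            stats.norm.ppf(config.binary[var]["male"]),
        )

    binaries: dict = {}
    lam = config.htn_bp_loading
    e = rng.standard_normal(n)
    binaries["on_htn_meds"] = (
        -(lam * state["z"]["sbp"] + np.sqrt(1 - lam**2) * e) < _per_sex_threshold("on_htn_meds")
    ).astype(float)
    for var in ("smoker", "corticosteroids", "alcohol_ever", "alcohol_current"):
        p = np.where(female, config.binary[var]["female"], config.binary[var]["male"])
        binaries[var] = (rng.random(n) < p).astype(float)

    frailty = rng.standard_normal(n)
    lam_f = config.fh_frailty_loading
    for var in _FH_VARS:
        e_k = rng.standard_normal(n)
        latent = lam_f * frailty + np.sqrt(1 - lam_f**2) * e_k
        binaries[var] = (latent < _per_sex_threshold(var)).astype(float)
    state["binaries"] = binaries
    state["fh_count"] = sum(binaries[v] for v in _FH_VARS)

    rk = config.risk
    state["eta_lin"] = (
        rk["age"] * state["z"]["age"]
        + rk["bmi"] * state["z"]["bmi"]
        + rk["waist"] * state["z"]["waist"]
        + rk["fh_count"] * state["fh_count"]
        + rk["female"] * female.astype(float)
    )
    state["u_member"] = rng.random(n)
    state["z_fpg"] = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    rho = config.glucose["rho_fpg_g2h"]
    state["z_g2h"] = rho * state["z_fpg"] + np.sqrt(1 - rho**2) * eps
    state["sex_key"] = sex_key
    return state


def _glucose_from_state(config: SimConfig, state: dict, intercept: float):
    """FPG, 2-h glucose and tail membership for a given risk intercept."""
    female = state["female"]
    member = state["u_member"] < expit(intercept + state["eta_lin"])
    fpg = np.empty(state["n"])
    g2h = np.empty(state["n"])
    g = config.glucose
    base_mean, base_sd = g["base_g2h"]
    tail_mean, tail_sd = g["tail_g2h"]
    for sex, mask in (("male", ~female), ("female", female)):
        if not mask.any():
            continue
        d = member[mask]
        w = float(d.mean())
        mean_t, sd_t = config.continuous_fpg(sex)
        mb, sb = g["tail_fpg"][sex]
        if w >= 1.0:
            mu_a, var_a = mean_t, sd_t**2  # degenerate: everyone in the tail
        else:
            mu_a = (mean_t - w * mb) / (1.0 - w)
            var_a = (sd_t**2 + mean_t**2 - w * (sb**2 + mb**2)) / (1.0 - w) - mu_a**2
            var_a = max(var_a, g["min_base_var"])
        # Base (non-elevated) glycaemia lives strictly below the fasting
        # diagnostic threshold; its conditional moments are solved from
        # the realised tail fraction so the marginal matches the target.
        z = state["z_fpg"][mask]
        base_mean, base_sd_eff, _, _ = _feasible_truncnorm(
            mu_a, float(np.sqrt(var_a)), 0.5, 6.99
        )
        base_vals = _truncnorm_from_z(z, base_mean, base_sd_eff, (0.5, 6.99))
        fpg_sex = np.where(d, _lognormal_from_z(z, mb, sb), base_vals)
        fpg[mask] = np.clip(fpg_sex, 0.5, None)
        zg = state["z_g2h"][mask]
        g2h_sex = np.where(
            d,
            np.clip(tail_mean + tail_sd * zg, 2.5, None),
            _lognormal_from_z(zg, base_mean, base_sd),
        )
        g2h[mask] = g2h_sex
    return fpg, g2h, member


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimConfig, seed: int | None = None, n: int | None = None,
    inject_missing: bool = True,
) -> pd.DataFrame:
    """Generate a participant roster; reproducible from (config, seed)."""
    n = int(n if n is not None else config.n_total)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = _draw_latents(config, n, rng)
    fpg, g2h, _ = _glucose_from_state(config, state, config.risk["intercept"])
    prior = (rng.random(n) < config.frac_prior_diagnosis).astype(float)

    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(1, n + 1)],
            "sex": np.where(state["female"], "female", "male"),
            "age": state["x"]["age"],
            "height": np.round(state["x"]["height"], 3),
            "weight": np.round(state["x"]["weight"], 1),
            "bmi": state["x"]["bmi"],
            "waist": state["x"]["waist"],
            "sbp": state["x"]["sbp"],
            "dbp": state["x"]["dbp"],
            "on_htn_meds": state["binaries"]["on_htn_meds"],
            "smoker": state["binaries"]["smoker"],
            "corticosteroids": state["binaries"]["corticosteroids"],
            "fh_mother": state["binaries"]["fh_mother"],
            "fh_father": state["binaries"]["fh_father"],
            "fh_sister": state["binaries"]["fh_sister"],
            "fh_brother": state["binaries"]["fh_brother"],
            "fpg": fpg,
            "glucose_2h": g2h,
            "prior_diagnosis": prior,
            "hdl": state["x"]["hdl"],
            "triglycerides": state["x"]["triglycerides"],
            "alcohol_ever": state["binaries"]["alcohol_ever"],
            "alcohol_current": state["binaries"]["alcohol_current"],
        }
    )
    if inject_missing and config.missing_rates:
        df = inject_missingness(
            df,
            mechanism=config.missing_mechanism,
            rates=config.missing_rates,
            seed=rng.integers(0, 2**31 - 1),
            mar_driver=config.mar_driver,
        )
    return df


def empirical_prevalence(config: SimConfig, n: int, seed: int) -> float:
    """Screen-detected prevalence (WHO rule) on a fresh sample, no missingness."""
    df = generate_cohort(config, seed=seed, n=n, inject_missing=False)
    y = outcome_series(df)
    return float(y.mean())


def calibrate_outcome_intercept(
    config: SimConfig,
    target_prev: float | None = None,
    tol: float = 0.005,
    n_cal: int = 100_000,
    lo: float = -8.0,
    hi: float = 4.0,
    max_iter: int = 60,
) -> SimConfig:
    """Bisect the latent-risk intercept until the large-sample prevalence
    (fixed calibration seed) is within ``tol`` of the target.

    Returns a new configuration with the calibrated intercept.
    """
    target = config.target_prevalence if target_prev is None else float(target_prev)
    if not 0.0 < target < 1.0:
        raise ConfigError("target prevalence must be in (0, 1)")
    if tol <= 0.0:
        raise CalibrationError("tolerance must be strictly positive")
    rng = np.random.default_rng(CALIBRATION_SEED)
    state = _draw_latents(config, int(n_cal), rng)

    def prev_at(a0: float) -> float:
        fpg, g2h, _ = _glucose_from_state(config, state, a0)
        pos = (fpg >= 7.0) | (g2h >= 11.1)
        return float(pos.mean())

    p_lo, p_hi = prev_at(lo), prev_at(hi)
    if not (p_lo < target < p_hi):
        raise CalibrationError(
            f"target {target} not bracketed: prevalence({lo})={p_lo:.4f}, "
            f"prevalence({hi})={p_hi:.4f}"
        )
    a, b = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        if prev_at(mid) < target:
            a = mid
        else:
            b = mid
    a0 = 0.5 * (a + b)
    achieved = prev_at(a0)
    if abs(achieved - target) > tol:
        raise CalibrationError(
            f"calibration stalled at prevalence {achieved:.4f} for target {target}"
        )
    new_risk = dict(config.risk)
    new_risk["intercept"] = a0
    return dataclasses.replace(config, risk=new_risk)


def inject_missingness(
    roster: pd.DataFrame,
    mechanism: str = "MCAR",
    rates: dict | None = None,
    seed: int = 0,
    mar_driver: str | None = None,
    mar_slope: float = 1.0,
) -> pd.DataFrame:
    """Place missing markers on a roster.

    ``rates`` maps column names to marginal missingness probabilities; the
    special key ``"family_history"`` masks all four relative indicators
    jointly (one unanswered questionnaire block).  Under MAR the per-record
    missingness probability is a logistic function of the standardised
    driver variable, with the intercept solved so the marginal rate is
    preserved; the driver itself must be fully observed.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ConfigError(f"unknown missingness mechanism {mechanism!r}")
    rates = dict(rates or {})
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"missingness rate for {col!r} must be in [0, 1]")
    out = roster.copy()
    rng = np.random.default_rng(seed)
    n = len(out)

    if mechanism == "MAR":
        if mar_driver is None or mar_driver not in out.columns:
            raise ConfigError("MAR mechanism needs an observed driver variable")
        drv = out[mar_driver].to_numpy(dtype=float)
        if np.isnan(drv).any():
            raise ConfigError(f"MAR driver {mar_driver!r} has missing values itself")
        zdrv = (drv - drv.mean()) / (drv.std() or 1.0)

    def probs(rate: float) -> np.ndarray:
        if mechanism == "MCAR" or rate in (0.0, 1.0):
            return np.full(n, rate)

        def mean_rate(a: float) -> float:
            return float(expit(a + mar_slope * zdrv).mean()) - rate

        a = optimize.brentq(mean_rate, -40.0, 40.0)
        return expit(a + mar_slope * zdrv)

    for key, rate in rates.items():
        if rate == 0.0:
            continue
        mask = rng.random(n) < probs(rate)
        cols = list(_FH_VARS) if key == "family_history" else [key]
        for col in cols:
            if col not in out.columns:
                raise ConfigError(f"missingness target {col!r} not a roster column")
            out.loc[mask, col] = np.nan
    return out
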