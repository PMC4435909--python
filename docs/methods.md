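# Methods

This note documents the statistical procedures implemented in `riskval`,
the numerical conventions chosen where the literature is ambiguous, and
what the synthetic-data generator does and does not emulate.

## Outcome and cohort model

Screen-detected (prevalent undiagnosed) diabetes follows the WHO OGTT
rule: fasting plasma glucose ≥ 7.0 mmol/L and/or 2-h post-load glucose
≥ 11.1 mmol/L, both thresholds inclusive.  If one measurement is missing
and the other is below its threshold the outcome is *indeterminate* and
treated as missing — a negative classification requires both
measurements to rule diabetes out.  Eligibility runs in two fixed
stages: (1) drop participants with a prior diabetes diagnosis, (2) drop
records with a missing outcome or any missing required predictor.  The
identity `n_analysis + stage1 + stage2 = n_roster` always holds and is
asserted in tests.

One common analysis set is used for all models (required variables =
union of the models' predictors), mirroring standard practice of
validating every model on the same participants; a per-model
complete-case mode exists behind a flag and changes n per model.

Derived variables: a recorded BMI takes precedence over the
height/weight derivation (`weight / height²`); family-history summaries
(`fh_any`, parent/sibling category, count) are computed from the four
relative indicators and are conservative under partial missingness (a
count is unknowable if any relative is unrecorded, but "any" is known as
soon as one relative is positive); elevated blood pressure is
SBP ≥ 140 or DBP ≥ 90 mmHg.  Units are fixed at load time (years, kg/m²,
cm, mmHg, mmol/L); no automatic conversion is performed.

## Model specifications

Risk models are declarative YAML: intercept, terms and link.  Terms are
`identity` (β·x), `indicator` (β if the value equals a declared
category) or `binned` (strictly increasing cut-points, one value per
bin; a value equal to a cut-point falls in the upper bin).  Integer
point scores (Omani, simplified Finnish) use the same machinery with a
documented score-to-probability logistic link `LP = a + b·score`, so
every model yields a predicted probability and intercept adjustment
applies uniformly.  Sex never passes through a numeric coding: indicator
terms name the category (`male`/`female`) explicitly, which removes the
classic 0/1-coding mismatch by construction.

Provenance of the bundled coefficients: the Cambridge score is a
transcription of the published logistic equation (the ex-smoker term is
dropped because the cohort dictionary records current smoking only).
The published equations of the Kuwaiti, Omani, Rotterdam-1 and
simplified-Finnish models were not available for transcription when the
files were authored; those four files are **synthetic reconstructions**
— the predictor sets exactly match the published model descriptions, and
coefficients were chosen once to give plausible risk gradients and the
qualitative calibration behaviour each model shows in high-prevalence
settings (e.g. strong underestimation by the simplified Finnish score).
Each file says so in its header and `provenance` field.  Because they
are data, replacing them with the published values requires no code
change, and no numerical result asserted by the test suite depends on
them.

## Performance metrics

**C statistic.** `c = [#concordant + ½·#ties] / #(event, non-event)
pairs`, computed by sorted-search in O(n log n) and verified against
O(n²) enumeration in tests.  The 95% CI uses the nonparametric variance
of the concordance estimator assembled from per-subject structural
components (`var = var(V10)/n₁ + var(V01)/n₀`).  The same components
give the paired test for two correlated C statistics (difference over
its nonparametric SE, normal reference); a paired-bootstrap alternative
is provided behind a flag and agrees with the analytic p-value on small
fixtures.  Pairwise model comparisons are reported with unadjusted
p-values plus a clearly-labelled Bonferroni column as an extension.

**E/O ratio.** `ΣP / Σy` with a Poisson log-scale 95% CI,
`ratio · exp(±1.96/√O)`.  The symmetric intervals printed in older
validation reports are not reproducible from O alone, so this dialect is
stated explicitly and used consistently.  Miscalibration percentages map
the ratio affinely: over-estimation `(ratio−1)·100` when ratio ≥ 1,
under-estimation `(1−ratio)·100` otherwise, CIs transformed identically
(endpoints swap for the under-estimation direction so the interval stays
ordered).

**Brier score, Yates slope.** `mean((p−y)²)` and
`mean(p|y=1) − mean(p|y=0)`.  For a constant prediction equal to the
event rate the Brier score equals `prev·(1−prev)` exactly; this closed
form is a test oracle.

**Calibration curves.** Quantile bins of predicted risk (deciles by
default, configurable); per bin the mean prediction, observed rate and
count, plus the sorted prediction rug for frequency annotation.  Tied
predictions straddling a bin edge are merged; constant predictions
occupy a single bin.

**Thresholds.** Classification is positive iff `p ≥ threshold`
(boundary inclusive).  The optimal threshold maximises Youden's
J = sens + spec − 1 over the distinct predicted values (an exhaustive
grid with midpoints gives the same optimum — tested); ties break toward
the lower threshold, i.e. higher sensitivity.  Correctly classified
obeys `acc = sens·prev + spec·(1−prev)`.

**Display rounding.** Percentages to whole numbers, C and E/O to two
decimals, Brier/Yates to three; all stored values keep full precision.

## Recalibration

Intercept adjustment (recalibration-in-the-large):
`δ = logit(prev) − logit(p̄)` added to every linear predictor (for
point-score models, to the score link's intercept).  One-shot adjustment
is the default — because the logistic is nonlinear it does not exactly
equalise `p̄` and `prev`; an iterated variant exists for the convergence
test (|p̄−prev| < 1e−8 within 50 iterations).  Discrimination is
invariant (monotone map), the optimal threshold is re-estimated on the
adjusted probabilities, and adjustment is fitted on the same data it is
applied to (in-sample, flagged in the adjusted model's provenance note).

## Multiple imputation

Chained equations with 10 cycles and m = 5 completed datasets by
default: continuous variables by normal-model draws (coefficients from
an approximate posterior, scaled-inverse-χ² residual variance), binary
variables by logistic-model draws (approximate-posterior coefficient
draws, marginal-Bernoulli fallback under separation).  Sex enters every
conditional model as an indicator; the glucose measurements are included
as predictors of missing covariates and are themselves imputable —
records whose outcome rests on imputed glucose are retained and counted
in the report.  Observed cells are never altered (asserted bitwise).
Pooling reports the per-dataset C statistics, their mean and min–max
spread; Rubin's-rules variance pooling is out of scope because the
sensitivity question is point similarity with the complete-case result.

## Synthetic cohort generator

The generator emulates a community screening sample: 78.7% female;
per-sex means/SDs for age, BMI, waist, SBP, DBP, height, weight, HDL,
triglycerides and fasting glucose taken from the published cohort
profile; per-sex prevalences for medication, smoking, corticosteroid
use, alcohol and the four family-history indicators; a 173/1256
prior-diagnosis fraction; and missingness rates chosen once so the
expected stage-2 exclusion fraction is ≈ 346/1083, concentrated in the
family-history block (the variables hardest to collect in routine
screening), with smaller rates on 2-h glucose, waist, smoking, weight
and FPG.

Continuous covariates come from a Gaussian copula with moment-matched
marginals: truncated normals solved by root-finding so the *truncated*
distribution has the target mean/SD (age is clamped to the plausible
15–95 y range), and a moment-matched lognormal for triglycerides.  The
rank-correlation defaults (BMI–waist 0.8, SBP–DBP 0.7, age–SBP 0.35,
BMI–weight 0.85, …) are documented choices, **not** derived from the
published study, which prints marginal summaries only; the matrix is
eigenvalue-clipped to the nearest PSD matrix if a user override breaks
positive-definiteness.  Antihypertensive treatment loads on the SBP
copula score (probit, loading 0.4) so treatment tracks pressure with the
marginal prevalence preserved exactly; family-history indicators share a
per-participant frailty factor (loading 0.5).  Height, weight and BMI
are generated as correlated marginals rather than deterministically
linked, so `bmi` ≈ but ≠ `weight/height²` record-by-record — the
recorded-BMI-wins precedence rule makes this harmless downstream.

The outcome is produced through the glucose measurements, never as a
direct Bernoulli label, so the WHO classification path is exercised
end-to-end.  A latent risk score (loadings 0.55 age, 0.45 BMI, 0.25
waist on copula z-scores, 0.35 per affected relative, 0.30 female)
selects membership of an elevated-glycaemia component.  Fasting glucose
is a per-sex two-component mixture: a lognormal elevated tail
(male mean 7.6 SD 2.0; female 8.3 SD 2.89) and a base component
constrained below the 7.0 mmol/L fasting threshold, whose conditional
moments are solved from the realised tail fraction so the *marginal*
FPG mean/SD equal the configured targets; keeping the base strictly
sub-threshold makes prevalence monotone in the latent intercept, which
is what lets simple bisection calibrate it.  When a far-from-equilibrium
tail fraction makes the base moments infeasible the SD target shrinks
geometrically (never at the calibrated operating point).  2-h glucose is
not summarised in the published profile; it is component-conditional
(base lognormal mean 5.5 SD 1.5, elevated normal mean 12.8 SD 3.0),
correlated 0.5 with the FPG deviate, and calibrated only through the
prevalence target.

`calibrate_outcome_intercept` bisects the latent intercept on a fixed
internal calibration sample (n = 100,000, fixed seed constant, 60
bisection steps) until the empirical screen-detected prevalence matches
the target (default 17.6%, tolerance 0.005); the shipped default
intercept (−1.9133) is the output of that calibration on the default
configuration.  Missingness injection supports MCAR and MAR (logistic in
a standardised observed driver, intercept solved so the marginal rate is
preserved).

**What the generator does not emulate.** Only the printed marginals and
the prevalence are targeted: the joint distribution (correlations,
interactions, measurement error, household structure beyond the
family-history frailty) is invented, 2-h glucose is calibrated only in
aggregate, and prior diagnosis is independent of the covariates.  A
model's C statistic or E/O on synthetic cohorts therefore demonstrates
that the *pipeline* computes these quantities correctly, not what the
model would achieve on the real population; passing tests validate
arithmetic and invariances, never substantive performance claims.

## Problem sizes and numerical conventions

The test suite exercises rosters of 1,256 (the study-scale default) and
recovery checks at n = 100,000, where every per-sex marginal mean/SD is
required to fall within 3 Monte-Carlo standard errors of its target (SE
of the SD via the fourth-moment formula) and the calibrated prevalence
within 0.5 percentage points.  Oracle-equivalence suites run 1,000
random instances (n ≤ 200) against O(n²) enumeration and exhaustive
threshold grids.  Ties in predictions count half in the concordance
statistic; probabilities at [0, 1] boundaries are accepted; empty
rosters yield zeroed exclusion logs rather than errors; degenerate
inputs (single-class outcomes, zero observed events) raise typed errors
that the pipeline converts into "undefined" report cells so a subgroup
without events never aborts a run.

## Known limitations

Reconstructed coefficients for four of the five bundled models (above);
Poisson log-scale E/O intervals as the single CI dialect; no
decision-curve or reclassification analysis; no slope recalibration or
model refitting (intercept adjustment only, by design); MAR injection
supports a single driver variable; Rubin's-rules pooling not
implemented.
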