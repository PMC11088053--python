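# Methods

`icutrials` implements an hourly sequential target-trial emulation for the
question "does immediate intubation, compared with waiting, change 30-day
and one-year mortality in acute hypoxemic respiratory failure?", together
with a synthetic ICU cohort generator that provides a known ground truth
for every stage. This note documents the models, the defaults and why they
were chosen, and what the synthetic experiments do and do not demonstrate.

## The emulated trial

**Eligibility.** A patient-hour is *included* when, at the start of the
hour, the SpO2/FiO2 (SF) ratio is ≤ 200 with SpO2 ≤ 97%, the patient is in
a medical, medical/surgical or coronary ICU, and has not been intubated.
It is *excluded* when respiratory rate > 39 breaths/min, GCS ≤ 12,
SF < 88, or the patient is not full code. All inequalities are exactly as
written (SF = 200 is included; SF = 88 is not excluded). A patient enters
the sequential trials at the first eligible hour provided it occurs within
48 h of ICU admission; hours are 0-based integers, hour h covering
[h, h+1), and "within 48 h" is read as first eligible hour ≤ 48.

**Missing data.** Physiological variables are imputed by last observation
carried forward (LOCF), per patient, never backwards. A criterion whose
input is still missing afterwards is handled conservatively: inclusion
criteria are not satisfied, exclusion criteria are not triggered, and the
variable is logged. A complete-case variant skips LOCF and drops rows with
residual missingness.

**Nested trials.** Every eligible, not-yet-intubated patient-hour k (k =
1..48 since first eligibility) contributes one trial observation: treated
if intubation occurs during that hour, control otherwise; after a treated
observation the patient contributes nothing further. Controls intubated at
a *later* hour are retained uncensored — an intention-to-treat-like
contrast per trial. A censor-at-crossover variant exists for sensitivity
use but is not the primary analysis. Patients who lose eligibility and
meet the criteria again re-enter later trials (their trial index keeps
counting from first eligibility, so gaps appear as skipped indices).

**Outcomes.** Time zero is each trial's baseline hour (fractional days).
Death is measured from there, administratively censored at 365 days;
30-day mortality censors at 30 days. ICU and hospital length of stay are
stay-level secondary outcomes summarized by weighted medians.

## Weighting and effect estimation

The hourly propensity to be intubated is one pooled logistic regression of
the treated indicator on trial index, age, Elixhauser score, FiO2, SF
ratio, respiratory rate, GCS, any-vasopressor use (dose > 0), and
admitting unit (categorical); continuous covariates enter linearly.
Stabilized weights use the fitted probability from a reduced logistic
model of treatment on trial index alone as numerator — stabilization that
respects the nested-trial time structure; a marginal-constant numerator is
selectable. Weights are untruncated by default (symmetric percentile
truncation is available behind a flag). Overlap weights (1−e for treated,
e for controls) exactly balance the weighted means of every propensity
model covariate, a property the tests verify to numerical precision.

Because the default numerator conditions on trial index, stabilized
weights balance confounders *given* the trial hour; marginal standardized
mean differences of the vitals shrink several-fold but need not fall below
the usual 0.1 rule of thumb, while the marginal-numerator variant drives
all of them below 0.1. The balance report states both.

The primary estimator is a weighted Cox proportional-hazards model of
treatment plus systolic/mean/diastolic blood pressure, temperature,
creatinine, bilirubin and platelet count, with a sandwich variance
clustered on patient to absorb the multiplicity of same-patient
observations. Ties are handled by Efron's method (event times are
continuous here, so the choice is immaterial; it is recorded in the result
metadata). Marginal survival curves are obtained by standardization: the
fitted model's predicted survival is computed for every observation under
each arm assignment and averaged with the analysis weights; adjusted risks
at 30/365 days are read off these curves, and their confidence intervals
come from a bootstrap that resamples *patients* (clusters), refitting the
expansion, the propensity model and the outcome model in every replicate.

AIPW and TMLE provide doubly robust sensitivity estimates of the one-year
mortality odds ratio (risk differences are also emitted). Both use
logistic nuisance models over the union of the propensity covariates and
the Cox adjustment covariates, a propensity floor of 0.01 (floored rows
are counted), and influence-curve variances clustered on patient. TMLE
uses a single intercept-free logistic fluctuation on the clever covariate
A/e − (1−A)/(1−e), which keeps its arm risks inside [0, 1]; AIPW risks can
in principle leave the unit interval and are flagged if they do.

## The synthetic cohort generator

Each patient carries a latent severity Z ~ N(0, `severity_sd`²). Hourly
vitals are AR(1) processes (autocorrelation 0.9; slow labs 0.98) around a
time-varying mean that moves from an admission level to a
severity-determined level after a random onset lag (Gamma(2, 2.5 h),
capped at 36 h) with a fast time constant (0.05–0.25 h), and decays back
in 90% of patients (recovery time constant 3–18 h starting 0–8 h after
onset). This makes eligibility switch on a few hours after admission
(median ≈ 5 h, IQR 3–7) and later switch off for most, giving a median of
about 7 trials per patient — matching the reported cohort shape.

While non-intubated, intubation fires each hour with probability
`expit(-3.95 + confounding_strength*Z - 0.05*(SF-150) + 0.08*(RR-24))`
(defaults shown). With the default `confounding_strength = 0`, treatment
depends only on the *recorded* vitals: confounding by indication is fully
measured and the analysis propensity model is correctly specified, which
mirrors the identifying assumption of the emulated trial. Nonzero values
open an unmeasured-confounding channel for sensitivity experiments.

The slope −0.05 per SF point was chosen so that assignment probabilities
stay inside a supported range (stabilized weights below ≈ 35). A much
steeper, near-threshold rule reproduces the near-immediate intubation of
the sickest patients but destroys positivity — true inverse-propensity
weights in the thousands — making IPW meaningless at any sample size. The
compromise shows up as a median in-trial intubation delay of ≈ 3 h (IQR
1–6) rather than ≈ 0: confounding strength realistic, overlap preserved.
About 26–27% of first-eligible patients are intubated during an eligible
trial hour.

Death times follow a constant baseline hazard (default 0.0014/day)
multiplied by `exp(severity_mortality_strength*Z + ψ*A(t))` where ψ =
`true_log_hr` and A(t) switches to 1 at intubation. The constant-hazard
form cannot match a real ICU cohort's front-loaded mortality: defaults
reproduce the one-year level (~42% among the eligible) but understate
30-day mortality (~5%). Thirty-day analyses therefore run on fewer events
in the synthetic world than they would on real data.

Intubation adds a configurable 2 days to the ICU stay (the planted effect
used by the length-of-stay recovery test). Missingness is MCAR,
independently per cell (default 5%); real chart missingness is informative
and burstier, so LOCF performance here is optimistic. Devices are
assigned by severity percentile (≈75% facemask, with HFNC and NIV in the
upper tail); code status is a stay-level constant (95% full code).

## The marginal-HR oracle

Hazard ratios are non-collapsible, so the pipeline's IPW-weighted HR is
benchmarked against a counterfactual simulation, not against exp(ψ): the
same patients are simulated under "intubate at first eligibility" and
"never intubate" (shared exponential draws), and an unadjusted two-group
Cox model on the stacked pair gives the marginal HR. At the default
frailty (`severity_mortality_strength = 0.6`) and ψ = log 0.8 the oracle
is ≈ 0.81.

Two structural gaps separate the pipeline estimand from this oracle, and
both exist in any real sequential emulation: (i) control observations of
patients intubated at a later hour keep their post-crossover protection
(intention-to-treat dilution), and (ii) the person-trial pseudo-population
differs from the first-eligibility population. At the defaults these
gaps are small (≈ +0.01 to +0.08 on the log scale, within the estimator's
per-replicate Monte-Carlo SD at n = 2000), and the recovery test asserts
exactly that: the weighted estimator's bias is within its Monte-Carlo
error while the crude estimator's bias is many times its own.

## Problem sizes and numerical choices

Monte-Carlo suites run at n = 2000 patients × 100 replicates (estimator
recovery), n = 1000 × 200 (null CI coverage), and n = 10,000 × 100
(double-robustness, on a dedicated point-treatment scenario with a known
closed-form truth computed at n = 400,000). The oracle uses 150,000
simulated patients. Logistic fits fall back to a light ridge penalty
(α = 1e-3) under separation and flag it; propensities are clipped to
(1e-10, 1−1e-10); the TMLE fluctuation that fails to converge reports ε=0
with a warning. Bootstraps are seeded and deterministic; every artifact
file carries the run's configuration hash and seed.

## Known limitations

- Constant baseline death hazard (see above): 30-day quantities are
  event-poor in synthetic cohorts.
- The generator's joint vital distribution is stylized; it is built to
  exercise the analysis (dynamic eligibility, LOCF, confounding by
  indication), not to be a physiological simulator.
- MCAR missingness only; no informative-missingness mechanisms.
- No competing-risk treatment of ICU discharge; survivors are followed to
  365 days regardless of location.
- The censor-at-crossover variant renormalizes weights but does not
  implement inverse-probability-of-censoring weighting; it is a
  sensitivity tool, not a per-protocol estimator.
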