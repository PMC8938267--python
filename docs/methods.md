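# Methods

`postacute` implements an observational target-trial-emulation pipeline for
estimating relative risks (hazard ratios) and 12-month absolute burdens of
incident post-acute outcomes in an exposed cohort against a contemporary and
a historical control group, together with a synthetic EHR cohort generator
whose ground truth the pipeline's validation batteries recover. This note
describes the statistical model, the generator, the estimators, the
numerical choices, and the known limitations.

## Study design

Each person has an index date T0: the exposure date for the exposed group,
and an assigned date for controls drawn so that the enrollment-date
distribution matches the exposed group (shifted back 730 exact days for the
historical group). Analyses are landmarked: only persons alive strictly
beyond T0 + 30 days enter, and the clock starts at day 30. For each outcome
an incident subcohort excludes anyone with the outcome in the 365 days
before T0; first occurrences inside the acute window (T0, T0 + 30 d] make a
person prevalent at the origin and are excluded by default
(`CohortSpec(acute_window="retain")` keeps such persons at risk instead —
the data record first occurrences only, so their acute event is simply not
counted). Follow-up ends at death, the outcome, a configured censoring
event (e.g. first vaccination), or the group's administrative end of
follow-up (2021-10-31; 2019-10-31 for the historical group).

Composite outcomes take the earliest component event. For MACE-style
composites that include all-cause mortality, death is a component event;
for every other outcome death is a competing risk: it censors the
cause-specific risk set and terminates the Aalen–Johansen survival factor.

## Synthetic cohort generator

The generator (`simulate.py`) produces persons, long-format first-event
records, and a sparse long-format code-occurrence table.

Confounding structure. Five latent standard-normal factors surface as
observed covariates — age, smoking category (ordered thresholds), health
care utilization counts (Poisson with a log-normal rate), area deprivation
(ADI), and BMI. In the exposed group the factors are mean-shifted
(`confounder_effect_on_exposure`), so the true exposure log-odds is exactly
linear in the observed covariate transforms; the same transforms enter
every cause-specific log hazard (`confounder_effect_on_hazard`). The
utilization factor is exposure-neutral by default because a tilt on the
latent Poisson rate would make the true exposure model non-logistic in the
observed counts, i.e. it would push the truth outside the fitted propensity
class; utilization still carries a hazard effect, so it must be modelled
for efficiency but not for bias. Remaining covariates (sex, race, eGFR,
blood pressures, comorbidity flags) are noise or age-linked and carry no
independent hazard effect.

Event law. Each outcome has a single first-event process with a
piecewise-constant hazard on the calendar timeline: the clock starts
`clock_back_days` before the enrollment anchor at rate `h0·exp(lp)`, and
from T0 the exposed hazard is multiplied by `exp(beta)` (per care setting
when a mapping is supplied). With the default `clock_back_days = 365`
(equal to the lookback), every pre-T0 event is visible to the history
exclusion, so the post-landmark cohort is exactly event-free and its
residual event times are exactly exponential — which is what makes the
closed-form oracles exact. Difference-in-differences worlds use a longer
runway (1100 d) so the pre-exposure period contains events; the resulting
first-event depletion before the lookback window creates a small "immune"
fraction, identical in distribution across groups given covariates, which
cancels in rate ratios and is negligible against sampling error in hazard
ratios at the sizes used.

Controls and T0. The spec-level contract is that controls leave the
generator without a T0; their event processes are anchored at a latent
enrollment date drawn from the same distribution. The pipeline by default
adopts that latent anchor as the assigned control T0 (`control_t0 =
"latent"`), which is distributionally identical to re-drawing from the
exposed empirical distribution (`assign_control_t0`, available via
`control_t0="resample"`) but keeps each person's timeline coherent:
re-drawing would misalign the lookback window with the window in which
pre-T0 events were generated and create immortal subjects whose first event
predates the lookback, deflating control rates by a few percent.

Missingness is MCAR at `missing_rate` (default 5%) on BMI, eGFR and blood
pressures — the covariates that are genuinely missing in EHR practice —
while demographics, smoking and utilization are always observed. Hazards
use the true values; the analyst sees the masked table. Care settings
(non-hospitalized / hospitalized / ICU) follow the reported 85.6 / 10.9 /
3.5% split. Sparse codes (540/543/62 per domain by default) get log-uniform
base prevalences in [0.002, 0.15]; one fifth are age-linked so the
high-dimensional screen has real signal. Baseline event rates and the
death rate (8e-5/day ≈ 2.9%/year) are arbitrary defaults in a plausible
range for an older, comorbid population; no external source fixes them.

## Covariates

Continuous covariates are imputed by conditional (within-group) means and
expanded in restricted cubic splines — the standard truncated-power
construction, linear beyond the boundary knots, 4 knots at quantiles (0.05,
0.35, 0.65, 0.95); count covariates are log1p-transformed first, and a
covariate whose knot quantiles coincide (e.g. mostly-zero counts) falls
back to its linear term. Categorical covariates are reference-coded.

The high-dimensional screen keeps codes occurring in at least `min_count`
persons in each comparison group (100 at full scale; scaled with cohort
size in the demonstration), computes the univariate relative risk of
exposure per code, and keeps the top k (100 primary; 300 and 0 as
sensitivity settings) by |log RR|, so protective and risk-elevating codes
both qualify; `rr_ranking="raw"` ranks by RR directly. Zero cells get a
0.5 continuity correction. Ties break lexicographically by (domain, code),
which makes selection invariant to row order. Selection is re-run per
outcome subcohort and per comparison.

## Weighting

The estimand-defining weight is the inverse odds of target-population
membership, w = p/(1−p), standardizing each comparison arm to the target
population — here the pooled exposed + contemporary groups. The pipeline
does not fit the "target vs arm" stacked regression literally: when the
target is a mixture of the sampled groups, the stacked model's true
log-odds is log(Σ_{g∈T} n_g f_g / n_arm f_arm), a softplus-shaped function
of the linear index that a main-effects logistic cannot represent (measured
consequence before the change: residual SMD ≈ 0.018 and log-HR bias ≈
+0.015 at n = 200,000). Instead a multinomial (softmax) group-membership
model — correctly specified when each pairwise log density ratio is linear,
as in the generator — yields the identical quantity exactly:

    w_arm(x) = Σ_{g ∈ target} P(g | x) / P(arm | x),

which equals the stacked target-vs-arm odds including the sampling
constants. In care-setting-stratified runs the exposed group is labelled
by setting, so each stratum is standardized by its own density
(P(stratum|x) in the denominator); the pooled "all" arm uses the sum of
its member-class probabilities. A row whose own-class probability falls
below 1e-6 triggers a positivity/separation error that names the offending
columns. Weights are untruncated by default; an upper-percentile
truncation (`weight_truncation_pct`) is available for stability.

Balance is reported as standardized mean differences with the pooled SD
computed on the unweighted sample, so before/after comparisons share a
denominator; |SMD| < 0.1 is the conventional adequacy threshold.

## Survival estimation

Hazard ratios come from a weighted Cox partial likelihood written in this
package: Efron tie handling (matching `survival::coxph`), Newton iterations
with step-halving on the exact (shift-invariant) weighted log-likelihood,
and a cluster-robust sandwich variance treating each person as a cluster —
appropriate because the weights are estimated. Score residuals use the
counting-process accumulator with Efron-averaged risk-set means, which is
exact without ties and agrees with R's robust SEs within ~1% under
day-resolution ties. The same core accepts delayed-entry (start, stop]
episodes, which is how vaccination enters as a time-varying 0→1 covariate
(episode splitting; person-level clusters). Doubly robust runs pass the
design matrix into the model alongside the weights. Deaths enter as
censored rows, which is precisely the cause-specific risk-set convention.
Significance is a 95% CI excluding 1.

Burdens are weighted Aalen–Johansen cumulative incidences at 365 days,
scaled per 1,000 persons, with death as the competing event; with no
competing events the estimator reduces exactly to 1 − Kaplan–Meier.
Excess burden is the exposed-minus-control difference; confidence
intervals come from a person-level bootstrap within arms (default 500
resamples, multinomial weight multipliers, percentile intervals).

## Difference-in-differences

Each person's pre-exposure window has exactly the length of their realized
post-exposure follow-up and ends at T0; the pre-period subcohort excludes
persons with the outcome in the year before the window start. Incident
rate ratios (weighted events over weighted person-time, exposed vs control)
are computed per period, with both arms weighted to the common target on
pre-exposure covariates, and the ratio of post- to pre-period IRRs cancels
time-invariant group differences. The analytic CI adds log-scale
Poisson-type robust variances across periods (treating periods as
independent, which ignores the person overlap); `did_ci="bootstrap"`
resamples persons jointly across periods and is used in the validation
batteries. In the exponential world rates equal hazards, so the ratio of
IRRs estimates the same exp(beta) as the Cox model.

## Control batteries

Outcome controls re-run the identical pipeline with only the outcome
substituted: negative controls (true HR 1) must be non-significant at about
the nominal per-control rate, a positive control must be detected. The
negative-exposure control assigns T0 from each person's influenza-vaccine
date and contrasts odd- versus even-numbered calendar days of that date —
a partition that cannot be causal — through the same design and weighting.
Every control carries its a-priori expectation; the report records HR, CI,
expectation and verdict, plus the shared configuration hash that makes the
"same design, only the substitution differs" property auditable. No
multiplicity correction is applied at the family level (reported only).

## Validation batteries and problem sizes

The `validation` module fixes the study conditions the test suite and
`scripts/acceptance.py` run at: parameter recovery (25 cohorts of
50,000/group, true HRs 1.7 and 1.0, active death hazard; weighted mean
log-HR bias < 0.02 while crude bias exceeds 0.05), CI coverage (200
replicates of 5,000/group for the weighted Cox HR and the bootstrap DiD
ratio), the closed-form competing-exponentials burden check at n = 100,000
(CIF(365) = h1/(h1+h2)·(1−e^−(h1+h2)·365) within 3 binomial SEs), balance
(max |SMD| < 0.1 at 10,000/group), graded severity (true HRs 1.2/1.8/2.5
across care settings at 20,000/group; the per-stratum event counts put
every pairwise ordering ≥ 3 SEs apart, so 50 replicates recover the strict
ordering ≥ 95% of the time), the control batteries, and byte-identity of
repeated runs. Code counts are reduced (or zero) in batteries that do not
exercise the high-dimensional screen. These sizes are the package's own
validation conditions; the demonstration analysis under `analysis/` uses a
single 12,000/group world.

## Numerical and degenerate-case choices

* All randomness flows from `numpy.random.SeedSequence`; identical
  configuration + seed reproduce byte-identical output tables (spawned
  seeds are kept below 2^31).
* Dates are day-resolution; event times are floored to whole days, so Cox
  fits see ties (handled by Efron) and determinism survives CSV round-trips.
* Newton convergence: gradient sup-norm below 1e-9 × (number of events);
  the linear predictor is max-shifted before exponentiation.
* SMD of a constant covariate is 0 when means agree and an error otherwise;
  zero-variance design columns are dropped with their metadata.
* A subcohort arm with no events, an empty subgroup, or an aliased
  time-varying indicator (everyone switched at entry) raise informative
  errors; subgroup tables mark such cells inestimable rather than dropping
  them.
* Horizons beyond the longest follow-up and censoring dates before entry
  are rejected (the latter drop the person with a counted warning).

## What the generator does not emulate

Real ICD/ATC/LOINC semantics and code co-occurrence structure; informative
(covariate- or outcome-dependent) censoring; time-varying baseline hazards
or effects beyond the two-piece constant form; recurrent events;
measurement error in covariates other than MCAR missingness; and
unmeasured confounding — by construction every confounder is observable, so
passing batteries show the machinery is correct and efficient, not that
weighting would remove bias in data where the exposure model is unknowable.
Coverage results inherit the usual property that the sandwich treats
estimated weights as fixed; at the validation sizes the measured coverage
is nominal (94–95%).
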