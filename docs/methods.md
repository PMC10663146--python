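# Methods

## The problem

When the exposure of interest is a *change* between two visits — here,
weight change between enrolment and a first follow-up two years later —
the analyst of observational data must decide (i) where to put time zero
and (ii) which confounder measurements to adjust for: those at enrolment,
those at the first follow-up, or both.  Different choices change the
estimand and carry different biases.  This package implements the three
strategies in common use and the machinery to measure their bias and
confidence-interval coverage by simulation.

* **Method 1** — time zero at enrolment, no exclusions, adjustment for
  enrolment covariates only.  Its person-period records for the first
  interval already carry the exposure observed at the *end* of that
  interval; this conditioning on the future is the method's defining flaw.
  It also retains subjects whose weight loss was caused by an emerging
  illness that itself raises short-term risk (reverse causation), so the
  apparent effect of weight loss is inflated.
* **Method 2** — time zero at the first follow-up; subjects with an event
  during the first interval are excluded; adjustment for follow-up
  covariates (plus the fixed enrolment covariates: age, sex, family
  history, baseline weight).  Exposure and eligibility are now aligned,
  but confounders measured at enrolment are ignored, leaving the backdoor
  path exposure ← C0 → outcome open; the modelled follow-up shrinks to
  18 years.
* **Method 3** (recommended) — time zero at enrolment with the first
  interval as a structural zero-risk *baseline period*; the same
  exclusions as method 2; adjustment for confounders measured at **both**
  waves.  All backdoor paths represented in the generator are closed.
  The price is a form of immortal time: subjects must reach the first
  follow-up event-free to be enrolled, which is why the first two years
  are reported as risk-free rather than modelled.

## Outcome model

Discrete-time survival via pooled logistic regression on person-period
records: for subject *i* at risk in interval *t*,

    logit P(Y_it = 1 | at risk) = α_t + β_L · loss_i + β_G · gain_i + γ' X_i

with one indicator α_t per modelled interval (a saturated
piecewise-constant baseline hazard — this matches the generator's truth
and removes baseline-hazard misspecification from bias measurements),
exposure indicators for loss and gain (maintenance is the reference), and
the method's covariate set X. Because per-interval event probabilities
are kept under ~5%, β_L and β_G read as log hazard ratios; a Cox fit on
the same data agrees to about 0.01 (checked as a test property).
Inference is Wald with model-based (inverse-information) standard errors:
the pooled logistic likelihood is a genuine likelihood here, there being
no weighting or clustering, and coverage statements refer to this
convention.  Non-convergence and quasi-separation (runaway coefficients
or exploded standard errors) are flagged on the result object, never
silently ignored.  Continuous covariates (age, baseline weight) enter
linearly and centered — centering only shifts the interval intercepts but
keeps hazard predictions numerically stable.

## Synthetic cohorts

`SimParams` defaults define the study conditions: 10,000 adults aged
45–60, BMI uniform on [25, 29.9), followed 10 × 2-year intervals with no
death before the outcome and no loss to follow-up.  Weight change between
enrolment and first follow-up is categorised at ±5% of baseline weight
(loss ≤ −5%, gain ≥ +5%, maintenance otherwise — the only reading that
makes the three categories exhaustive and disjoint).  True conditional
effects are injected on the interval-logit scale: 0 for loss and 0.3 for
gain versus maintenance; they act only from interval 2 onward, since the
exposure does not exist during the interval in which it forms.

Confounding structure (all coefficients are package choices; the
magnitudes below are the defaults in `SimParams`):

* **Smoking** (prevalence 25%, 2-year persistence 0.85, initiation 0.03)
  raises the hazard at both waves (log-OR 0.35 / 0.40) and pushes toward
  loss and away from gain (±0.3 at enrolment, ±0.7 at follow-up).
* **Diuretic use** (prevalence 15%) is an indication marker for
  hypertension: strong hazard effects (0.6 / 0.35) and strong effects on
  the exposure (loss +0.8 / gain −0.4 at enrolment). Its between-wave
  persistence is deliberately moderate (log-odds bump 1.2), so the wave-0
  measurement is *not* recoverable from the wave-1 measurement — this is
  what gives method 2 a visible residual bias.  Had both confounders been
  nearly static, adjusting for either wave would have sufficed and
  methods 2 and 3 would have been indistinguishable.
* **Chronic disease** with onset in interval 1 (incidence 5%) strongly
  increases weight loss (log-odds +2.5) and the interval-1 hazard
  (log-OR +2.2).  This reverse-causation channel is confined to
  interval 1: methods 2 and 3 neutralise it entirely by excluding
  first-interval events, while method 1 absorbs it as spurious
  loss-associated risk.  Letting it persist into later intervals would
  confound every method — including method 3, whose covariate set is
  fixed and does not contain chronic disease — and the design goal of the
  generator is precisely that method 3's adjustment set closes every open
  backdoor path. Excluding subjects with first-interval chronic disease
  (rather than only first-interval events) is available as an option,
  mirroring eligibility criteria that restrict to "healthy" weight change.
* Age (hazard +0.04/year), male sex (+0.3), family history (+0.4) and
  baseline weight (+0.01/kg) act as fixed covariates available to every
  method; they are adjusted everywhere and contribute no differential
  bias.

Baseline interval logits are constant at −4.35, giving a per-interval
event probability of ~2% at covariate means (validated to stay ≤5%), a
20-year cumulative risk of ~20%, and ~2.5–3% of subjects excluded by
methods 2/3 for a first-interval event.  Exposure-category intercepts are
set so the cohort splits roughly 28/46/26 between loss, maintenance and
gain; every category stays above 10% so each method's regression is
estimable at every replicate.

Under these defaults the expected qualitative pattern emerges: method 3
is unbiased for both contrasts with ~95% coverage; method 2 carries a
moderate positive bias for loss and small negative bias for gain; method
1 is worst, biased upward for loss (reverse causation plus unadjusted
follow-up confounders) and downward for gain.  The bias *ordering* and
*signs* are properties of the causal structure and are asserted by tests;
the bias *magnitudes* depend on the coefficient values chosen here and
are reported, not asserted.

What the generator does **not** emulate: death as a competing risk,
loss to follow-up or censoring of any kind, continuous-time event
processes, measurement error in weight, time-varying exposure after the
first follow-up, or confounders that evolve over the full 20 years.
Passing tests therefore demonstrate the logic of the emulation methods
under a clean, known data-generating process — not performance on real
healthcare databases, where all of the above complications apply.

## Curve estimators

Both marginal-curve estimators operate on the post-exclusion cohort and
target the same standardized cumulative incidence per exposure group:

* **IPW-weighted Kaplan–Meier** — a three-category multinomial logistic
  exposure model (log-odds linear in the method's covariate set) yields
  fitted probabilities; each subject gets the stabilized weight
  (marginal category share) / (fitted probability of own category).
  Stabilized weights average ~1 within each group (asserted empirically),
  and mean/max weights are reported as diagnostics.  Fitted probabilities
  below 0.01 raise a warning naming the number of affected subjects;
  optional truncation clips weights at their 1st/99th percentiles.  The
  weighted Kaplan–Meier estimate is computed on the method's clock.
* **Parametric g-formula** — per-subject per-interval hazards are
  predicted from the fitted pooled-logistic model with the exposure
  indicators forced to each level, converted to cumulative risk via the
  product of conditional survival probabilities, and averaged over the
  retained subjects.  The default model imposes a proportional
  (interval-constant) exposure effect, matching the replication study's
  estimand; exposure-by-interval interactions are available via the
  `flexible` flag.

For method 3 both curves start at enrolment and are flat at zero through
year 2 (the baseline period is structural — no degenerate all-zero
outcome rows enter the regression, and the likelihood is unaffected).

## Replication harness

`run_replications` spawns one child seed per replicate from the master
seed before any work starts (numpy `SeedSequence`), so serial and
parallel execution give identical reports.  Per method and contrast it
reports mean estimate, bias against the injected truth, empirical SD,
95%-CI coverage, and Monte-Carlo standard errors (SD/√R for bias,
√(p(1−p)/R) for coverage).  Replicates whose fit fails to converge or
separates are dropped from summaries and counted (expected ~0 at the
default sample size).  Truth for bias is the injected conditional
logit-scale effect; the small pooled-logistic-vs-Cox gap is covered by a
separate concordance property rather than folded into bias.

## Problem sizes and numerical choices

The headline simulation study uses 500 replicates of n = 10,000 — at
coverage 0.95 this puts the Monte-Carlo SE of coverage near 1 percentage
point and of bias near 0.003, enough to separate the methods' biases
cleanly.  The null-confounding check runs 200 replicates at n = 2,000:
bias there is structural (zero) and needs no larger n.  Oracle-equivalence
checks run on ≤500-record instances with a 3-interval design so every
interval indicator keeps events (with 10 intervals and ~50 subjects some
interval always has none, and the saturated baseline separates).
Newton–Raphson is the optimizer throughout; the independent test oracle
is a from-scratch Newton iteration on the written-out likelihood,
agreeing to 1e−6 (1e−8 on the hand-built example).  The 97.5% normal
quantile is frozen at 1.959964.  Ties in the category draw at the ±5%
boundary have probability zero under the uniform within-band draws; the
classifier itself uses closed inequalities (≤ −5%, ≥ +5%).

## Known limitations

* Bias magnitudes for methods 1–2 are functions of the chosen confounder
  coefficients; only their ordering and signs are structural.
* Method 3 still embeds the immortal-time restriction (subjects must
  survive interval 1 event-free); its estimand is risk among those
  reaching the first follow-up event-free, reported with a 2-year
  zero-risk head.  Cloning/censoring/weighting fixes do not apply when
  the strategy is only knowable at the first follow-up.
* Weight change remains a proxy exposure: nothing in the simulation or
  the estimators distinguishes *how* weight was lost; the chronic-disease
  exclusion narrows, but does not close, that gap.
* No bootstrap or delta-method uncertainty for the marginal curves —
  point estimation only.
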