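# Methods

This note documents the statistical procedure, the synthetic-data
generator, the numerical choices, and the design decisions that were
genuinely open.

## Study design

The pipeline reproduces a matched retrospective cohort design on
administrative claims. An *incident hip fracture case* is a person's
first inpatient claim with an ICD-10 code S72.0 (femoral neck), S72.1
(pertrochanteric) or S72.2 (subtrochanteric) as the primary diagnosis,
inside a configurable enrolment window (default 2005-01-01 to
2013-12-31) and at age ≥ 50 in the index year; any earlier S72.0–S72.2
claim in any position or setting marks the person as non-incident and
excludes them. The claim's first day of care is the index date.

Each case is matched to up to four reference subjects of the same sex
and birth year who, at the case's index date, are alive, inside their
insurance-coverage window, and free of any prior fracture claim.
Sampling is without replacement across the whole study, so
`references = 4 × cases − total shortfall`. Follow-up for everyone runs
from the index date to death or the study closure date (default
2016-05-04); subjects dying on the index date are credited half a day at
risk. A reference subject who fractures *after* the index date stays in
the reference arm for that matched set (eligibility is defined strictly
before the index date) and can found their own case record.

### Order of matching

Cases are processed in chronological index-date order, with ties broken
randomly by the run seed, and each case draws its references uniformly
at random from the currently eligible, unused candidates. The
chronological order matters: when cases are processed in arbitrary
order, a case processed early consumes long-lived candidates that
later-processed, earlier-index cases cannot replace, while candidates
who die young remain available only to early-index cases — the selected
reference group then dies measurably faster than the population it is
drawn from. Processing in index order makes pool consumption depend only
on survival up to dates that every current candidate has already
reached, so selection is independent of post-index survival. (In a real
national database the candidate pool is so much larger than the demand
that the effect is negligible; in simulated populations of 10⁴–10⁵ it
is not.)

## Comorbidity

The Charlson comorbidity index is computed from ICD-10 claims using the
Quan coding algorithm's 17 condition categories (packaged as an editable
prefix table, `data/charlson_map.csv`). Two weight tables ship: the 2011
re-estimated weights (default) and the original 1987 weights
(selectable). Hierarchy pairs — mild vs moderate/severe liver disease,
any malignancy vs metastatic solid tumour, diabetes without vs with
complications — are resolved so only the severer member scores.

Evidence rules, evaluated over the half-open window
`[index − 365 days, index)` plus the index claim itself:

1. secondary/other diagnoses coded on the index-date inpatient claim
   count (its primary diagnosis — the fracture — does not);
2. any diagnosis on an inpatient claim in the window counts;
3. an outpatient diagnosis counts only if the category appears on two or
   more outpatient claims whose dates are ≥ 7 days apart, read as the
   *maximum pairwise* date difference (the weakest reading consistent
   with "two or more times at least 7 days apart"; the rule guards
   against rule-out and duplicate coding).

Matching codes is prefix-based on the dotted upper-case form. The bulk
scorer is a vectorised implementation; its agreement with the
rule-by-rule reference implementation is itself under test. CCI enters
the adjusted model as an integer covariate truncated at 10.

## Mortality model

Follow-up is split on a graduated interval grid — cut-points every 0.5
months to 3, monthly to 12, quarterly to 24, half-yearly to 48 and
yearly to 120 months (29 cut-points) — chosen so the short early
intervals can resolve the steep post-fracture mortality peak. Each
subject contributes full widths to intervals survived and a partial
width to the interval containing end of follow-up; the death indicator
sits in that interval. Follow-up past 120 months is truncated.
Person-time conservation is exact and is property-tested at 1e-9 months.

*Crude model.* Saturated in arm × interval, so maximum-likelihood rates
equal cell deaths / person-time; the implementation uses this closed
form, and its equality with the iteratively fitted GLM (to 1e-8) is kept
as a test rather than a runtime path. Cells with zero person-time carry
a missing rate and are skipped in chaining with a warning; cells with
zero deaths keep their informative zero rate.

*Adjusted model.* Log-linear Poisson with main effects of fracture, CCI,
age (continuous, centred at the cohort mean) and interval, plus
fracture×interval, fracture×CCI, fracture×age and interval×age
interactions, with log person-time offset. Subject-interval rows are
aggregated over identical covariate patterns first (likelihood
invariant). Fitting uses IRLS with a 1e-8 tolerance and at most 100
iterations; non-convergence raises. A pattern with no deaths anywhere
triggers a separation warning and the fit continues unpenalised. The
reference level for the interval factor is the first interval, so the
fracture main effect is the log rate ratio in the first half-month at
the covariate centre.

*Risks.* Interval rates map to probabilities via `1 − exp(−λΔ)` and
chain multiplicatively. Adjusted curves are *marginally standardised*:
rates are predicted for every covariate pattern of the case arm, chained
into a per-pattern survival curve, and the risk curves averaged over
patterns for both arms. Standardising both arms to the case-arm
covariate mix makes the case−reference contrast an exposed-standardised
(attributable) comparison. Averaging interval *probabilities* across
patterns before chaining — a plausible alternative reading — was
rejected because under covariate heterogeneity it overstates cumulative
risk materially (about 18 points at 120 months on a 20,000-person
synthetic cohort): a subject's interval survivals chain within subject,
so curves must be chained per pattern first. Stratified analyses
(e.g. by sex) fit per stratum and average the stratum curves weighted by
case counts.

## Effect measures and bootstrap

Excess risk, risk ratio and attributable fraction are computed from the
two arms' cumulative risks at a horizon; their defining identities
(AF = 1 − 1/RR, etc.) hold to machine precision and are property-tested.
Public outputs are percentages at one decimal.

The bootstrap resamples whole matched sets — a case with its references
— preserving the matched design; matching is not redone inside
replicates. Risks and risk differences get bias-corrected (BC)
intervals: the percentile interval shifted by the median-bias constant
`z₀ = Φ⁻¹(#{θ* < θ̂}/B)`, with no acceleration term (BCa's jackknife
acceleration is omitted for determinism and simplicity). Risk ratios get
plain percentile intervals. For the crude model, per-set exposure cells
are precomputed so a replicate is a single weighted sum — 400 replicates
cost milliseconds; the adjusted model refits per replicate. Replicates
with an undefined statistic (empty reference cell before the horizon)
are redrawn up to a 5% failure budget, then the run aborts. A risk ratio
whose bootstrap coefficient of variation exceeds 0.5 is flagged
unreliable in the output (the threshold is a package choice; reported
ratios are never suppressed).

## Synthetic-data generator

The generator emulates the raw material of a national claims mortality
study of a Baltic-scale 50+ population; every planted quantity has a
closed-form truth function.

* **Population.** Sex ratio 41% male; ages at the data start drawn from
  10-year band weights (0.36/0.28/0.21/0.11/0.04 from 50–59 to 90+);
  coverage spans the data window (2004-01-01 to 2016-05-04).
* **Comorbidity.** Independent Bernoulli category prevalences (the
  `estonia_like` preset gives a mean true CCI near 0.7); the
  hierarchy-resolved updated-weight score multiplies both the death
  hazard (default HR 1.4 per point) and the fracture hazard (default
  HR 1.3 per point), planting the comorbidity–fracture confounding the
  adjusted model is meant to remove.
* **Mortality.** Gompertz baseline per sex, `λ₀(a) = b·exp(θa)` per
  person-year with θ = 0.095 and b = 3.2e−5 (men) / 1.75e−5 (women) —
  about 2.5%/year for a 70-year-old man, rising e-fold per ~10.5 years.
* **Fracture.** Incidence per person-year piecewise constant over sex ×
  10-year age bands (preset: 0.8–2.5 per 1000 at 50–69 rising to 18–25
  per 1000 at 90+).
* **Post-fracture effect.** Multiplicative hazard ratio
  `h(u) = 1 + A·exp(−u/τ) + B` at `u` months after fracture. The preset
  A = 18, τ = 2, B = 0.5 gives a large immediate excess decaying over a
  few months onto a persistent 1.5-fold plateau, and puts crude 1-year
  case mortality in the 20–35% band the preset is designed for (the
  preset is a convenience, not a calibration claim).
* **Claims.** Each true category emits outpatient (3/person-year) and
  inpatient (0.15/person-year) claims with representative codes while
  the person is alive; fractures emit inpatient claims with primary
  S72.0/1/2 in a 55/35/10 mix and occasional comorbid secondary
  diagnoses; background noise claims use non-Charlson codes. A
  configurable fraction of persons (default 15%) receives a *decoy*
  category whose claims deliberately fail the 7-day outpatient rule
  (a single visit, or a pair < 7 days apart) — the scorer must exclude
  them, and a test verifies it does.

Death times are drawn by exact inversion of the closed-form cumulative
hazard (analytic for the pre-fracture branch; 80-step vectorised
bisection, accurate to ~1e-9 months, for the post-fracture branch), and
a person fracturing before their provisional death time restarts with
the multiplied hazard — valid sequential sampling for a Markov hazard.
Sampled data and truth functions therefore describe exactly the same
process.

**Truth for a realised cohort.** The case-arm truth averages the exposed
closed-form risk over case subjects' true covariates. The reference-arm
truth depends on the contrast: for the crude comparison it is the
*marginal* risk — unexposed at index but with a possible future fracture
integrated out over the planted incidence (composite Simpson quadrature,
240 panels; the integrand has kinks at age-band crossings, and 240
panels agree with 1920 to ~1e-6) — because reference subjects are only
required to be fracture-free up to the index date. Conditioning on the
*realised* fracture time instead would bias the truth: observing that a
subject never fractured is informative about early death. For the
standardised (adjusted) contrast the reference truth is the case arm's
counterfactual never-fracture risk.

**What the generator does not emulate.** Real claims exhibit coding
drift over calendar time, provider-level coding habits, correlated
comorbidity clusters, emigration, and insurance lapses; diagnoses here
are conditionally independent given the planted categories and coverage
is complete. Passing recovery tests therefore demonstrates the
*pipeline's* correctness under the stated hazard structure, not
robustness to real-world coding pathology.

## Validation suite and problem sizes

The test suite checks, besides per-module unit and property tests:

* effect-measure identities on the published cohort's printed inputs;
* closed-form/oracle equivalences (saturated fit vs GLM at 1e-8,
  constant-rate chaining at 1e-12, piecewise risk vs a Kaplan–Meier
  oracle within 0.5 points at every cut-point on a > 5,000-subject
  simulated cohort);
* parameter recovery on 50,000-person populations: crude 5-year excess
  risk within 1.5 points of analytic truth, fracture main effect within
  3 SE of log 2 under a constant doubled hazard, and all fracture terms
  within 3 SE of zero under the null;
* bootstrap calibration: 95% BC intervals for the 5-year excess risk
  cover the per-cohort planted truth in 91–99% of 200 repetitions
  (populations of 5,000; 400 replicates each).

Problem sizes were chosen so the whole suite runs in minutes on a single
core while keeping Monte-Carlo noise well below the asserted tolerances.

## Known limitations

* Age is fixed at the index date in the adjusted model; attained age
  during the 10-year follow-up is not updated (the interval×age
  interaction absorbs part of this).
* The exact mechanics of within-age-group residual age adjustment used
  in the original analysis cannot be recovered from its description;
  marginal standardisation to the case arm's covariate distribution is
  this package's documented substitute.
* BC (not BCa) intervals; no delta-method alternatives; no multiplicity
  adjustment across horizons.
* No competing-risks decomposition, cause-of-death analysis, or
  emigration modelling; all-cause death only.
* The without-replacement matched design is itself slightly informative
  when the candidate pool is thin relative to demand (see *Order of
  matching*); chronological processing removes the selection bias but
  short matched sets still occur in the oldest strata.
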