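# Methods

## Model structure

Each of the five hazardous-prescribing indicators is modelled as a pair
of discrete-time cohort state-transition (Markov) models sharing one
state set. The cohort enters in an exposed "well" state; per-cycle
transition probabilities move it into adverse-event states, post-event
states, a ceased-exposure well state, or death (absorbing, utility 0,
cost 0). State sets follow the adverse events relevant to each
indicator:

* **Gastrointestinal models** (older adults, previous peptic ulcer, and —
  with a stroke pathway added — oral anticoagulant): well, GI
  discomfort, symptomatic ulcer, serious GI event (e.g. a bleed), a
  post-GI-event state with a rebleed probability, (stroke and
  post-stroke for the anticoagulant model), ceased-exposure well, death.
* **Heart failure**: well, minor exacerbation, major exacerbation
  requiring hospital admission, ceased-exposure well, death.
* **Chronic kidney disease**: well, AKI managed in primary care, AKI
  requiring hospital admission (with or without renal replacement),
  reduced residual kidney function, progressed CKD (including renal
  replacement therapy, with high ongoing cost and mortality),
  ceased-exposure well, death. Natural CKD progression applies in both
  arms, so comparator-arm survivors can still progress to the expensive
  state — this is what lets long-horizon cost increments shrink or
  reverse, as longer-lived unexposed patients consume progression
  resources.

The comparator arm represents NSAID + gastroprotection (GI models) or
paracetamol substitution (anticoagulant, heart failure, CKD), modelled as
the baseline adverse-event risks with no NSAID-attributable excess.

### Arm parameterisation

Arm-dependent adverse-event transitions carry two parameters: the
comparator-level annual probability and a non-negative NSAID-attributable
excess probability. The two combine on the constant-hazard rate scale
(`rate_hpe = rate_base + rate_excess`, then `p = 1 − e^{−rate·Δ}`), so
the HPE arm is at least as risky as the comparator for **every** valid
parameter set and every probabilistic draw. This makes "all simulations
show patient harm" a structural property rather than a statistical
accident, which matches how the indicators are defined: the hazardous
event is, by definition, exposure that adds risk.

### Exposure and cessation

Hazardous prescribing is assumed to continue for the whole horizon
unless an adverse event occurs, in which case it stops. Cessation after
an event is structural: event states are one-way tunnels into post-event
states (or the ceased-exposure well state) whose onward transitions use
comparator-level parameters; cohort mass never returns to the exposed
state. Event-specific sequelae (rebleeding, post-AKI progression) apply
equally in both arms once the event has occurred. Limited exposure
duration — review and cessation without an event — is modelled by
switching the exposed cohort to comparator transition probabilities once
the assumed duration has elapsed; durations must sit on the cycle grid
(the quarterly grid supports the 0.25-year scenario).

## Engine conventions

* **Cycle length**: configurable; default 1 year (annual utilities and
  costs, 5/10/20-year horizons), quarterly supported. Annual
  probabilities are rescaled to the cycle via constant hazards,
  `p_Δ = 1 − (1 − p_1)^Δ`.
* **Discounting**: `(1 + r)^{−kΔ}` with `r = 0.035` by default.
* **Accrual**: occupancy at cycles 1..N accrues; the entry distribution
  at cycle 0 accrues nothing, so an always-occupied state yields exactly
  `horizon × utility` undiscounted. A half-cycle correction (average of
  adjacent cycle occupancies) and cycle-0 accrual are available behind
  flags; all flags are echoed in result metadata. Defaults keep the
  accounting transparent and exactly checkable against closed forms.
* **Validation**: transition rows must sum to 1 within 1e-9 with entries
  in [0, 1] and absorbing rows the identity. Renormalisation is refused —
  an invalid row is an error naming the row, because silent fixes would
  hide parameter-file mistakes.

## Probabilistic sensitivity analysis

Probabilities and utilities are sampled from beta distributions, costs
from gamma distributions, each moment-matched to (mean, SD). SD comes
from a reported SE, from 95% CI bounds as `(hi − lo)/3.92`, or defaults
to 20% of the mean when no measure of uncertainty is available.
Parameters at a boundary (utility 1, probability 0) are held fixed,
since beta moment-matching is undefined there. All parameters are drawn
independently; each sample applies one draw of every parameter to both
arms, so shared baselines are identical within a sample. A sampled
vector that overflows a transition row is rejected and redrawn whole
(rejections counted and reported) rather than truncated, to avoid
silently biasing means. The base case uses 10,000 samples; credibility
intervals are empirical 2.5th–97.5th percentiles with linear
interpolation between order statistics. The cost-effectiveness-plane
summary reports quadrant proportions and a 95% bivariate-normal ellipse
(sample mean/covariance at the chi-square(2) 0.95 radius).

## National scaling

Indicator prevalence uses the audited England practice sample
(10,906,453 registered patients): rate per 1000 = 1000 × count /
denominator, with a normal-approximation (Wald) binomial CI — this
convention reproduces the published interval for the largest indicator
(1.68–1.73 per 1000) — and Wilson intervals behind a flag. National
counts scale the sample proportion (and its CI endpoints) to the
63,049,603 GP-registered patients. National totals multiply counts by
per-person increments *per PSA sample* and then summarise, so grand
totals are exactly additive across indicators in every sample and the
intervals reflect parameter uncertainty. Display rounding: counts
half-up to integers, rates to 2 dp, £ totals to 2 dp in £m, QALY totals
to integers.

The overlap-minimisation scenario deducts the anticoagulant, heart
failure and CKD at-risk counts from the older-adult at-risk pool and
reduces the older-adult affected count proportionally to the at-risk
reduction. The published adjusted results imply a somewhat larger
affected-count reduction than proportional, and the exact rule is not
recoverable; proportional deduction is used as the transparent choice,
so exact reproduction of the published adjusted row is not expected.

## Synthetic parameters

The original input evidence tables are not distributed, so the generator
produces stand-ins with the same structure: per-transition annual
probabilities, per-state utilities and annual GBP costs (cost-year
2020-21), each with a mixed uncertainty descriptor (SE, 95% CI, or none
— exercising the 20%-of-mean fallback) and a beta/gamma/fixed family
flag. Template magnitudes are clinically plausible for each indication
(e.g. ~1%/year serious GI bleed risk on an unprotected NSAID in older
adults, ~10% in-hospital AKI mortality, progressed-CKD costs dominated
by renal replacement therapy); values are jittered log-normally around
the templates per seed. The `paper_magnitude` preset constrains each
indication's deterministic per-person increments to the published
per-person ranges (QALY change within [−0.111, −0.014]; cost change
within [£14, £1097]) with bounded retries; the `default` preset jitters
more freely. Deterministic ground-truth increments are recorded at
generation time, and optionally a reference PSA mean, for recovery
checks (deterministic at 1e-9; PSA within 3 combined Monte-Carlo SEs).

What the generator does **not** emulate: correlation between parameters,
age- and sex-specific background mortality trajectories, time-varying
baseline risks, and the actual evidence-derived magnitudes. Passing
tests therefore demonstrate that the machinery is correct and that the
qualitative findings (all increments harmful, concave harm accrual,
horizon/discounting monotonicity) are structural — not that the
synthetic numbers reproduce the published per-person values.

The practice-level generator draws practice list sizes log-normally
(mean ≈ 10,290, the sample mean list size), at-risk counts binomially
within the list, and affected counts binomially within the at-risk pool,
so pooled rates converge to the per-1000 targets.

## Problem sizes used in the shipped checks

The test suite runs PSA legs at a few hundred samples and the
convergence checks at 10,000 distribution draws; these sizes give
Monte-Carlo error comfortably inside the asserted tolerances while
keeping the default run quick. The acceptance script's headline values
are exact arithmetic on published inputs and are preceded by a 200-sample
synthetic end-to-end self-check.

## Known limitations

* Cohort-level only: no patient-level heterogeneity, no tunnel-state
  memory beyond the explicit post-event states.
* No treatment benefit of NSAIDs is modelled — increments capture harm
  only, by design.
* Whether the original analyses used half-cycle correction is unknown;
  the default here is off, with the flag recorded in all outputs.
* National-total credibility intervals carry PSA uncertainty only;
  prevalence-sampling uncertainty is reported separately on the counts
  and not propagated into the totals.
* The weighted NSAID-mix scenario uses representative class relative
  risks and the 2022 England prescribing mix; it scales the whole
  HPE-arm event rate, so a strongly GI-protective mix could in principle
  bring the HPE arm below the comparator for a GI transition.
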