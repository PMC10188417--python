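# Methods

## Model structure and assumptions

The package implements a cross-sectional cohort model: each (country, year)
cell is an independent snapshot of women aged ≥70, with no individual
trajectories across years, no mortality, no fracture recurrence dynamics and
at most one fracture per type (hip, vertebral, non-hip non-vertebral) per
woman-year.  Outcomes are expected values — the main path draws no random
numbers; counts are real-valued and rounded half-away-from-zero only at the
reporting boundary.

Risk heterogeneity is represented by a two-stratum mixture rather than a
full individual-level risk distribution: a fraction `at_risk_share` of women
carries `at_risk_multiplier` times the baseline per-type probability.  This
is an explicit reconstruction: the treated subpopulation's risk distribution
in the underlying care pathway (assessment → identification of those at
risk → treatment) is not published, so treatment is assumed to target the
high-risk stratum first and spill over only when the treated fraction
exceeds the stratum.  Non-adherent treated women receive no treatment
benefit by default (`nonadherent_efficacy=0`); adherent women's per-type
probability is multiplied by the country's treatment-mix relative risk.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `assessment_rate_sq` | 0.25 | fraction | status-quo risk-assessment rate, all countries |
| `adherence_sq` | 0.40 | fraction | status-quo adherence to anti-osteoporosis medication |
| `at_risk_share` | 0.30 | fraction | stand-in model constant, not an estimate |
| `at_risk_multiplier` | 4.0 | ratio | per-type risk of the at-risk stratum vs baseline |
| `nonadherent_efficacy` | 0.0 | fraction of (1−RR) | partial benefit without adherence (sensitivity) |
| `med_cost_scaled_by_adherence` | false | — | charge medication only for adherent women |
| `assessment_mode` | `relative` | — | `relative`: a·(1+f); `gap`: a+f·(1−a) |

Country-level inputs (fracture-type mix, treatment-mix relative risks,
first-year fracture costs, annual medication cost, BMD measurement cost,
status-quo treatment rate, identification rate among assessed, treatment
rate among those identified) are read from CSV; the bundled fixture covers
Belgium, France, Germany, Ireland, Poland, Slovakia, Switzerland and the UK
with all monetary inputs in 2020 euros (a CPI utility exists but is never
applied by default).  Printed whole-percentage fracture mixes are
renormalised proportionally to sum to 1.

The `relative` default for the assessment lever follows the plain reading
of "an f% improvement in the assessment rate" and keeps a 100% improvement
from 25% at 50%; the `gap` mode is first-class because the adherence lever
is explicitly gap-closing and either convention is defensible.  Neither is
claimed to be "the" published convention.

## Calibration

Because the population-average probability is linear in the baseline
`b_t` below the probability cap, calibration is closed-form:
`b_t = q_t / D_t` with `q_t` the observed per-type incidence (total
incidence split by the fracture-type mix) and
`D_t = s·m + (1−s) − α_eff(1−RR_t)(w_at·m + w_nt)`.  Feasibility requires
`m·b_t ≤ 1`; infeasible targets raise a diagnostic error.  The status-quo
output is by construction invariant to the (share, multiplier) choice —
stratification redistributes risk without changing the mean — but
intervention deltas are not: the multiplier controls how much risk the
newly treated carry, hence the size of every intervention effect.

Cost calibration multiplies the fracture-cost component by a single factor
so the modelled total matches the observed total; the medication
(N·τ·c_med) and assessment (N·a·c_BMD) components remain structural.  The
assessment cost convention is one BMD measurement per assessed woman per
snapshot year, and medication is charged for all treated women regardless
of adherence; both conventions are configurable because the underlying
reporting is silent on them.

## Numerical choices

* Rounding: half-away-from-zero at display (counts to integers, per-100k
  fracture rates to integers, per-100k costs to €0.1M, percentages to one
  decimal), matching the published table conventions.
* Treatment rates produced by the uptake formula are clipped at 1 with a
  logged warning; probabilities are clipped into [0, 1] (the
  one-fracture-per-type cap).
* The FRAX-like generative function converts its baseline probability to a
  hazard (−log(1−p)) before applying the log-linear age term, the
  gradient-of-risk per T-score SD and the CRF multipliers, so the reference
  point (age 70, T-score 0, no CRFs) recovers the baseline exactly. Its
  coefficients are illustrative field-plausible constants, not fitted or
  published values.
* Microsimulation assignment is deterministic-by-quantile by default
  (highest-risk women treated first, mirroring the cohort targeting rule);
  a fully random assignment mode exists for sensitivity runs, in which
  treatment is untargeted and the cohort closed form is *not* its
  expectation.

## What the synthetic generator emulates — and does not

`SyntheticCountrySpec` draws country parameter sets and population
projections from ranges bracketing the bundled inputs, plus individual
covariates (age truncated at 70, T-score, binary clinical risk factors) for
the FRAX-like function.  It reproduces the *structural* assumptions of the
analysis (two-stratum risk, targeted treatment, one fracture per type per
year, exponential population growth).  It does not emulate real
epidemiology: no correlation between costs and incidence, no country-level
age-structure differences, no secular trends in treatment mix.  Passing
tests therefore demonstrate internal consistency of the equations and code,
not predictive validity on real populations.

## Known limitations

* Intervention-effect magnitudes depend directly on the stand-in
  stratification constants; with the default (0.30, 4.0) the at-risk
  stratum carries ≈2.1× the population-average risk, which is far weaker
  risk concentration than a FRAX-chart-based identification achieves, so
  modelled intervention effects are conservative.  In particular the
  assessment lever's avoided fracture costs do not cover its added
  medication and BMD spending under these defaults, and no realistic
  (share, multiplier) choice reverses that within this cost convention:
  cost savings from improved assessment require risk concentration in the
  newly treated far beyond what a two-stratum mixture at these defaults
  can express.
* No discounting, QALYs, indirect or post-first-year costs, adverse
  events, male population, or vertebral fracture assessment.
* The five snapshot years are modelled independently; nothing is said
  about intervening years.
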