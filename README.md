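# osteoburden

A population-level, cross-sectional cohort model of osteoporotic fracture
burden among women aged 70 years and over, for health-economics and
epidemiology analysts.  It projects annual fracture counts (hip, vertebral
and non-hip non-vertebral) and direct costs of care across countries and
snapshot years (2020–2040), calibrates the model to observed incidence, and
evaluates hypothetical disease-management interventions — improving the
fracture-risk assessment rate, improving adherence to anti-osteoporosis
medication, and their hierarchical combination — against the status quo.

## The model

For each country *c* and year *y*, women are split into a high-risk stratum
(share *s*, per-type annual fracture probability *m·b<sub>t</sub>*) and the
remainder (probability *b<sub>t</sub>*).  A fraction τ is treated (targeting
the high-risk stratum first); of those, the adherent fraction α has each
per-type probability multiplied by the treatment mix's relative risk
RR<sub>t</sub>.  The population-average probability per fracture type *t* is

    p_t = s·m·b_t + (1−s)·b_t − α·(1−RR_t)·(w_at·m·b_t + w_nt·b_t)

with (w_at, w_nt) the treated weights in each stratum, each woman recording
at most one fracture per type per year.  Expected fractures are N·p_t, and
annual costs of care are

    cost = Σ_t N·p_t·c_t  +  N·τ·c_med  +  N·a·c_BMD

(first-year direct fracture costs, annual medication cost for every treated
woman, one BMD assessment per assessed woman), all in 2020 euros.

Because p<sub>t</sub> is linear in b<sub>t</sub>, the baseline risks are
**calibrated in closed form** so the status-quo model reproduces observed
per-100,000 incidence exactly, and a single multiplicative factor on the
fracture-cost component aligns total costs.  Interventions then change the
management rates — assessment a (relative or gap-closing improvement),
treatment τ via the uptake formula

    τ_new = τ + (a_new − a_sq) × identification rate × at-risk treatment rate,

adherence α_new = α + f·(1−α) — and deltas versus the status quo give net
benefits.  A seeded individual-level microsimulation
(`osteoburden.synthetic`) reproduces the cohort equations woman-by-woman and
serves as the model's independent cross-check, alongside a FRAX-like
generative risk function (age, T-score, clinical risk factors) for
synthetic cohorts.

## Worked example

```python
from osteoburden import FractureBurdenModel

model = FractureBurdenModel.from_fixtures()   # bundled eight-country inputs
res = model.fit()                             # closed-form calibration
scen = res.run_scenarios()                    # levers × {10%, 50%, 100%}

sq = scen.aggregates["status_quo"]
print(round(sq[2020].fracture_total), round(sq[2020].cost_total, 1))
print(round(sq[2040].fracture_total), round(sq[2040].cost_total, 1))
```

prints

```
1238319 12790.0
1784300 18376.0
```

— about 1.24 million fractures and €12.8 billion of care in 2020 across the
eight bundled countries, rising to 1.78 million and €18.4 billion in 2040
(a 44% increase in both, driven by a 40% growth of the 70+ female
population).  Net benefits of the 50%-improvement scenarios in 2040:

```python
from osteoburden import AGGREGATE_CODE
for label in ("1_50", "2_50", "3_50"):
    nb = scen.net_benefits[label][(AGGREGATE_CODE, 2040)]
    print(label, round(nb.delta_fractures), round(nb.delta_cost, 1))
```

```
1_50 -6558 169.4
2_50 -46014 -476.3
3_50 -57490 -358.6
```

All levers prevent fractures, and the combined lever prevents the most.
Under the default stand-in risk stratification (30% of women at 4× risk)
the assessment lever's added medication and BMD-measurement spending
exceeds its avoided fracture costs, so its cost delta is positive; the
adherence lever, which adds no spending, saves €476M.  The magnitude of
intervention effects is governed by how strongly risk is concentrated in
the treated stratum — see `docs/methods.md`.

The same pipeline is scriptable:

```sh
osteoburden run --scenarios combined:0.5 --out outputs --format markdown
osteoburden synth --seed 1 --n-countries 8 --out synthetic/
```

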