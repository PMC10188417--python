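# Default pipeline configuration.  Values here mirror the documented
# defaults; a user config is layered on top, and CLI flags override both.
inputs:
  country_params: null   # null -> bundled fixture table
  population: null
  burden: null
assumptions:
  assessment_rate_sq: 0.25
  adherence_sq: 0.40
profile:
  at_risk_share: 0.30
  at_risk_multiplier: 4.0
options:
  nonadherent_efficacy: 0.0
  med_cost_scaled_by_adherence: false
  assessment_mode: relative   # or "gap"
scenarios: null   # null -> each lever at 10/50/100%; [] -> status quo only
seed: 0
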