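country_code,country_name,dist_hip,dist_vertebral,dist_nhnv,rr_hip,rr_vertebral,rr_nhnv,cost_hip,cost_vertebral,cost_nhnv,med_cost_annual,bmd_cost,treatment_rate_sq,identification_rate,at_risk_treatment_rate
BE,Belgium,0.21,0.14,0.65,0.62,0.46,0.83,13381,2959,4932,216,34,0.22,0.57,0.33
FR,France,0.21,0.14,0.64,0.55,0.43,0.71,13286,3312,7398,151,41,0.14,0.69,0.18
DE,Germany,0.20,0.15,0.65,0.60,0.45,0.82,19218,5585,9063,305,36,0.06,0.58,0.09
IE,Ireland,0.19,0.14,0.67,0.60,0.48,0.82,16247,3594,5996,252,99,0.29,0.48,0.47
PL,Poland,0.19,0.15,0.65,0.60,0.52,0.83,5606,1241,1950,85,10,0.08,0.51,0.12
SK,Slovakia,0.18,0.15,0.67,0.62,0.47,0.83,4690,1037,2047,173,32,0.13,0.41,0.25
CH,Switzerland,0.21,0.15,0.65,0.59,0.40,0.80,17954,11484,12063,468,98,0.27,0.76,0.36
GB,United Kingdom,0.16,0.12,0.72,0.61,0.56,0.84,11055,2756,6334,36,51,0.20,0.49,0.35
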