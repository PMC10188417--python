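country_code,year,population
BE,2020,909965
BE,2025,981569
BE,2030,1079222
BE,2035,1189198
BE,2040,1272290
FR,2020,5755944
FR,2025,6417296
FR,2030,7071131
FR,2035,7721280
FR,2040,8246896
DE,2020,7617401
DE,2025,8004192
DE,2030,8540931
DE,2035,9441730
DE,2040,10266513
IE,2020,266580
IE,2025,316146
IE,2030,370709
IE,2035,430199
IE,2040,487401
PL,2020,2808079
PL,2025,3313821
PL,2030,3812156
PL,2035,4025639
PL,2040,4076774
SK,2020,362914
SK,2025,432737
SK,2030,495271
SK,2035,537088
SK,2040,558324
CH,2020,665515
CH,2025,724290
CH,2030,798327
CH,2035,899196
CH,2040,996235
GB,2020,5082343
GB,2025,5475642
GB,2030,5914422
GB,2035,6475365
GB,2040,6911825
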