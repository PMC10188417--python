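country_code,year,fracture_count,cost_millions
BE,2020,48700,343
BE,2025,51500,365
BE,2030,56597,401
BE,2035,63674,448
BE,2040,70190,494
FR,2020,303133,4628
FR,2025,328918,5026
FR,2030,370321,5654
FR,2035,420066,6399
FR,2040,462294,7042
DE,2020,409939,4473
DE,2025,429444,4686
DE,2030,447562,4883
DE,2035,484442,5304
DE,2040,541024,5903
IE,2020,14768,132
IE,2025,17469,155
IE,2030,20952,185
IE,2035,24642,218
IE,2040,28494,250
PL,2020,85578,235
PL,2025,95823,264
PL,2030,111468,307
PL,2035,128478,352
PL,2040,140632,383
SK,2020,16868,48
SK,2025,19586,56
SK,2030,23181,65
SK,2035,26279,74
SK,2040,28028,78
CH,2020,50952,744
CH,2025,56590,824
CH,2030,63088,918
CH,2035,70596,1028
CH,2040,78878,1148
GB,2020,308381,2187
GB,2025,339412,2405
GB,2030,372077,2634
GB,2035,406832,2880
GB,2040,434760,3078
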