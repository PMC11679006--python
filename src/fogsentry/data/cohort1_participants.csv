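participant,age_years,years_since_diagnosis,nfogq,updrs3,froze,n_trials,total_trial_duration_s,n_fog,total_fog_duration_s,total_target_zone_s
P01,67,16,14,10,1,26,881.4,49,33.81,98
P02,80,11,21,20,1,26,1199.9,35,92.4,99.4
P03,71,11,17,13,1,29,1456.09,14,14.84,91
P04,64,10,4,18,0,14,547.96,0,0,
P05,70,14,20,13,0,24,1100.16,0,0,
P06,68,19,22,29,1,29,1964.46,10,42.3,155.4
P07,78,5,15,16,1,26,2024.62,221,335.92,410.2
P08,70,12,17,20,1,22,1057.76,24,36.24,127.4
P09,80,10,18,18,1,28,1445.36,9,6.75,98
P10,80,2,4,15,0,29,1251.64,0,0,
P11,72,5,19,20,0,29,1867.89,0,0,
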