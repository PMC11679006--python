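participant,age_years,years_since_diagnosis,nfogq,updrs3,froze,n_trials,total_trial_duration_s,n_fog,total_fog_duration_s,total_target_zone_s
P12,74,4,18,6.5,1,12,457.20,9,9.90,57.40
P13,66,19,29,28,1,29,1436.37,41,67.24,207.20
P14,69,19,15,17,1,27,1472.58,23,63.25,233.80
P15,81,3,19,14.5,1,28,1353.80,34,93.84,
P16,67,6,23,20.5,1,28,1872.08,28,370.72,
P17,58,11,29,20,1,26,1907.36,83,678.94,516.60
P05B,72,17,15,,1,23,1176.91,8,50.32,180.60
P07B,81,8,26,11,1,29,2268.96,126,496.44,676.20
P08B,73,14,10,10,1,29,1318.05,1,0.73,120.40
P11B,74,8,22,22,1,22,2461.80,75,324.00,
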