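dataset,n_participants,sensitivity_pct,specificity_pct,fog_identified_pct,fog_predicted_pct,fog_detected_pct,mean_id_s
1,11,75.40,83.08,74.31,40.61,51.93,-0.64
2,10,82.50,77.27,94.86,57.01,80.14,-1.10
3,21,77.68,79.99,86.84,49.11,68.48,-0.94
1a,10,55.31,88.56,59.57,30.50,40.43,-0.59
1b,7,78.32,82.16,79.28,44.48,53.31,-0.70
1c,6,69.17,86.17,78.01,37.59,52.48,-0.50
3a,20,77.07,80.66,89.98,53.25,72.58,-1.03
3b,17,77.42,80.39,85.95,47.97,67.85,-0.88
3c,16,76.27,80.52,89.81,53.08,71.53,-1.03
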