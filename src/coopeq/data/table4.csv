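session_id,trust_mean,trust_sd,grat_mean,grat_sd,lam,forecast_trust,forecast_grat
15.09.2015,5.38,3.48,3.17,2.54,0.15,4.39,3.63
21.09.2015,4.25,2.68,1.98,2.15,0.23,3.67,2.43
05.10.2015,3.33,1.36,0.94,0.69,0.34,2.81,1.55
09.10.2015,5.58,2.74,4.12,3.27,0.11,4.70,4.40
12.10.2015,5.80,3.03,4.87,3.75,0.09,4.89,5.08
19.10.2015,5.81,3.32,6.88,3.29,0.03,5.08,6.86
26.10.2015,4.06,3.28,2.62,2.07,0.21,3.89,2.74
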