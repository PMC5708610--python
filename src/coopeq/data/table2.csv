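session_id,coop_mean,coop_sd,lam
15.09.2015,0.121,0.13,1.334
21.09.2015,0.144,0.15,1.131
28.09.2015,0.409,0.31,0.139
05.10.2015,0.227,0.14,0.641
09.10.2015,0.364,0.21,0.228
12.10.2015,0.417,0.26,0.126
19.10.2015,0.356,0.26,0.244
26.10.2015,0.212,0.22,0.710
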