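session_id,coop_mean,coop_sd
15.09.2015,0.741,0.35
21.09.2015,0.537,0.33
28.09.2015,0.639,0.43
05.10.2015,0.574,0.35
09.10.2015,0.528,0.29
12.10.2015,0.718,0.33
19.10.2015,0.796,0.27
26.10.2015,0.556,0.37
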