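session_id,stage,n_coop,n_recoop,n_default,n_tolerant
15.09.2015,before,31,7,221,23
15.09.2015,after,70,61,26,12
21.09.2015,before,19,2,101,14
21.09.2015,after,53,39,43,17
28.09.2015,before,50,25,70,23
28.09.2015,after,131,100,73,30
05.10.2015,before,28,4,92,21
05.10.2015,after,119,90,85,28
09.10.2015,before,43,18,77,22
09.10.2015,after,109,73,95,34
12.10.2015,before,52,25,68,25
12.10.2015,after,147,120,57,25
19.10.2015,before,43,20,77,20
19.10.2015,after,76,65,20,13
26.10.2015,before,26,9,94,15
26.10.2015,after,112,91,92,22
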