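age_start,age_end,n,c
20,24,1952,16
25,29,1791,32
30,34,2113,73
35,39,2783,169
40,44,2274,223
45,49,2393,357
50,54,2090,521
55,59,1750,558
60,64,1136,478
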