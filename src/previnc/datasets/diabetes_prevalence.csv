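age_start,age_end,year,n,c
20,24,2009,19029,33
25,29,2009,19549,65
30,34,2009,19391,109
35,39,2009,20885,200
40,44,2009,28844,402
45,49,2009,28856,706
50,54,2009,25641,1145
55,59,2009,23223,1826
60,64,2009,18845,2134
65,69,2009,21964,3160
70,74,2009,22965,4281
75,79,2009,15944,3628
80,84,2009,13310,3114
85,89,2009,8796,2159
90,94,2009,2380,569
95,99,2009,892,188
20,24,2010,18939,36
25,29,2010,18917,69
30,34,2010,19388,122
35,39,2010,19722,208
40,44,2010,26543,403
45,49,2010,29509,742
50,54,2010,25870,1178
55,59,2010,23238,1850
60,64,2010,20112,2423
65,69,2010,19714,2887
70,74,2010,23452,4446
75,79,2010,16509,3909
80,84,2010,13083,3295
85,89,2010,8637,2220
90,94,2010,2760,681
95,99,2010,833,177
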