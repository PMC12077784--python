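age_start,general,breathlessness
20,481185,343937
25,478683,333343
30,476150,320446
35,472641,304305
40,467066,284325
45,457729,260806
50,441895,233060
55,415262,200561
60,372908,163241
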