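# Segi (1960) world standard population, Doll-Hill modification,
# restricted to ages 20+ with an open 80+ interval (weight 500 + 500 = 1000).
age_group_start,weight
20,8000
25,8000
30,6000
35,6000
40,6000
45,6000
50,5000
55,4000
60,4000
65,3000
70,2000
75,1000
80,1000
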