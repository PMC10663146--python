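id,arm,weight_change,chronic_first2y,cvd
1,a_low_caloric,loss,1,1
2,a_low_caloric,loss,1,0
3,a_low_caloric,loss,0,1
4,a_low_caloric,loss,0,1
5,a_low_caloric,loss,0,0
6,a_low_caloric,loss,0,0
7,a_low_caloric,loss,0,0
8,a_low_caloric,loss,0,0
9,a_low_caloric,loss,0,0
10,a_low_caloric,loss,0,0
11,a_low_caloric,loss,0,0
12,a_low_caloric,loss,0,0
13,a_low_caloric,loss,0,0
14,a_low_caloric,loss,0,0
15,a_low_caloric,loss,0,0
16,a_low_caloric,loss,0,0
17,a_low_caloric,loss,0,0
18,a_low_caloric,loss,0,0
19,a_low_caloric,loss,0,0
20,a_low_caloric,loss,0,0
21,b_standard_caloric,loss,1,1
22,b_standard_caloric,loss,1,0
23,b_standard_caloric,maintain,0,1
24,b_standard_caloric,maintain,0,1
25,b_standard_caloric,maintain,0,0
26,b_standard_caloric,maintain,0,0
27,b_standard_caloric,maintain,0,0
28,b_standard_caloric,maintain,0,0
29,b_standard_caloric,maintain,0,0
30,b_standard_caloric,maintain,0,0
31,b_standard_caloric,maintain,0,0
32,b_standard_caloric,maintain,0,0
33,b_standard_caloric,maintain,0,0
34,b_standard_caloric,maintain,0,0
35,b_standard_caloric,maintain,0,0
36,b_standard_caloric,maintain,0,0
37,b_standard_caloric,maintain,0,0
38,b_standard_caloric,maintain,0,0
39,b_standard_caloric,maintain,0,0
40,b_standard_caloric,maintain,0,0
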