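model,TP,FP,FN,TN
1,36,608,3,590
2,36,708,3,490
3,32,140,7,1058
4,30,322,9,876
5,26,277,13,921
6,18,172,21,1026
7,29,336,10,862
8,36,589,3,609
9,36,94,3,1104
10,34,365,5,833
11,34,23,5,1175
12,35,32,4,1166
13,36,40,3,1158
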