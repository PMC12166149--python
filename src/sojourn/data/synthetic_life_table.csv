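age,annual_rate
0,0.003225
1,0.001767
2,0.00102
3,0.000638
4,0.000444
5,0.000345
6,0.000297
7,0.000274
8,0.000264
9,0.000261
10,0.000262
11,0.000266
12,0.00027
13,0.000276
14,0.000282
15,0.00029
16,0.000297
17,0.000306
18,0.000315
19,0.000326
20,0.000337
21,0.000349
22,0.000362
23,0.000377
24,0.000392
25,0.000409
26,0.000428
27,0.000448
28,0.00047
29,0.000494
30,0.00052
31,0.000549
32,0.00058
33,0.000613
34,0.00065
35,0.00069
36,0.000733
37,0.00078
38,0.000832
39,0.000888
40,0.000949
41,0.001016
42,0.001088
43,0.001167
44,0.001252
45,0.001346
46,0.001447
47,0.001558
48,0.001679
49,0.00181
50,0.001953
51,0.002108
52,0.002277
53,0.002462
54,0.002662
55,0.002881
56,0.003119
57,0.003378
58,0.003659
59,0.003966
60,0.004301
61,0.004664
62,0.00506
63,0.005492
64,0.005961
65,0.006472
66,0.007029
67,0.007634
68,0.008294
69,0.009012
70,0.009794
71,0.010645
72,0.011572
73,0.01258
74,0.013679
75,0.014875
76,0.016177
77,0.017594
78,0.019137
79,0.020817
80,0.022646
81,0.024638
82,0.026806
83,0.029166
84,0.031736
85,0.034533
86,0.037579
87,0.040896
88,0.044506
89,0.048437
90,0.052716
91,0.057375
92,0.062448
93,0.06797
94,0.073982
95,0.080528
96,0.087655
97,0.095413
98,0.10386
99,0.113057
100,0.123069
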