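serial,mz,z,p_value,status
1,403.23,2,0.008,D
2,409.2,2,0.04,D
3,414.23,2,0.003,D
4,415.67,2,0.01,U
5,421.22,2,0.002,D
6,425.25,2,0.002,D
7,430.28,1,0.01,D
8,436.24,2,0.004,D
9,442.23,2,0.001,D
10,443.23,2,0.01,D
11,447.26,2,0.012,D
12,450.3,1,0.007,D
13,451.2,2,0.006,D
14,458.25,2,0.004,D
15,459.24,1,0.03,U
16,464.31,1,0.03,U
17,465.74,2,0.014,D
18,472.3,1,0.007,D
19,473.21,2,0.029,D
20,482.29,1,0.005,D
21,487.25,2,0.003,D
22,488.29,1,0.017,D
23,494.3,1,0.006,D
24,495.23,2,0.014,D
25,497.26,1,0.006,D
26,522.28,1,0.03,D
27,524.26,2,0.01,D
28,537.27,1,0.03,D
29,541.29,1,0.01,D
30,543.31,3,0.019,D
31,546.27,2,0.004,D
32,555.27,1,0.0002,D
33,568.27,2,0.001,D
34,571.25,1,0.0014,D
35,572.63,3,0.008,D
36,575.33,1,0.04,D
37,582.3,2,0.03,U
38,585.3,1,0.006,D
39,590.3,2,0.007,D
40,599.29,1,0.002,D
41,605.28,2,0.03,D
42,629.3,1,0.003,D
43,643.3,1,0.003,D
44,649.32,2,0.01,D
45,656.33,2,0.008,D
46,673.33,1,0.0018,D
47,687.35,1,0.002,D
48,700.36,2,0.003,D
49,709.4,1,0.02,U
50,713.47,1,0.02,U
51,717.35,1,0.002,D
52,721.37,2,0.005,D
53,721.42,1,0.008,U
54,722.37,2,0.002,D
55,731.37,1,0.002,D
56,743.37,2,0.02,D
57,744.3,2,0.04,U
58,747.3,1,0.02,D
59,761.37,1,0.004,D
60,792.58,1,0.019,U
61,819.43,1,0.003,D
62,835.38,1,0.005,D
63,863.43,1,0.002,D
64,879.43,1,0.015,D
65,923.45,1,0.0085,D
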