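pareto_id,bt_s,t_c,v_ms,dt_min,sec_mj_kg,vc_mg_100g,rc
1,93,89,1.2,366.7,1.43,4.19,3.35
2,93,88.8,1.21,369.7,1.49,4.21,3.35
3,93,88.5,1.24,375.5,1.56,4.24,3.35
4,95,88.4,1.2,379.5,1.59,4.31,3.37
5,93,86.9,1.16,387.5,1.82,4.4,3.32
6,95,88.7,1.1,389.0,1.53,4.27,3.37
7,95,87.0,1.18,389.9,1.82,4.42,3.34
8,94,85.9,1.14,397.5,2.01,4.49,3.3
9,93,83.2,1.19,407.7,2.5,4.71,3.24
10,94,87.9,0.9,412.8,1.68,4.31,3.34
11,96,83.1,1.21,419.5,2.59,4.79,3.25
12,94,86.6,0.89,423.5,1.92,4.43,3.32
13,96,83.0,1.15,425.1,2.62,4.8,3.25
14,95,87.6,0.82,430.7,1.76,4.38,3.35
15,95,86.0,1.54,434.5,2.35,4.5,3.32
16,96,83.8,1.51,448.6,2.78,4.72,3.27
17,92,89.8,0.42,457.3,1.31,4.11,3.36
18,93,89.8,0.35,463.0,1.29,4.13,3.37
19,95,85.2,1.73,463.8,2.74,4.58,3.3
20,95,89.9,0.34,472.3,1.30,4.17,3.4
21,95,84.5,1.85,483.4,3.04,4.65,3.29
22,95,85.5,1.93,486.1,2.91,4.55,3.31
23,95,84.0,1.88,492.2,3.21,4.7,3.27
24,95,84.4,1.99,500.5,3.23,4.66,3.29
25,95,85.1,2.11,510.2,3.22,4.59,3.3
26,95,84.5,2.11,513.7,3.36,4.64,3.29
27,95,84.5,2.16,520.5,3.43,4.65,3.29
28,95,84.8,2.21,524.7,3.44,4.62,3.29
29,95,84.5,2.23,529.5,3.54,4.65,3.29
30,95,84.6,2.35,542.0,3.66,4.64,3.29
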