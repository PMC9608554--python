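run,A,B,C,t_e_bup,t_b_imp2,t_e_imp2,t_b_imp3
1,39.00,45.00,9.00,9.35,9.39,9.65,9.93
2,41.00,45.00,7.00,7.93,7.93,7.93,8.00
3,39.00,60.00,11.00,9.79,9.83,10.13,10.41
4,41.00,45.00,11.00,8.05,8.05,8.05,8.15
5,37.00,30.00,9.00,10.43,10.56,10.85,11.12
6,41.00,30.00,9.00,7.19,7.19,7.47,7.56
7,39.00,60.00,7.00,9.75,9.83,10.03,10.31
8,37.00,45.00,11.00,11.34,11.43,11.81,12.23
9,37.00,45.00,7.00,10.98,11.01,11.21,11.39
10,39.00,45.00,9.00,9.33,9.38,9.65,9.95
11,37.00,60.00,9.00,11.90,12.02,12.37,12.59
12,39.00,45.00,9.00,9.35,9.41,9.61,9.96
13,39.00,45.00,9.00,9.35,9.41,9.68,9.99
14,39.00,30.00,7.00,8.63,8.68,8.93,9.14
15,41.00,60.00,9.00,8.11,8.11,8.39,8.53
16,39.00,30.00,11.00,8.62,8.67,8.92,9.19
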