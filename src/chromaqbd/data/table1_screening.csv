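run,A,B,C,D,E,F,t_e_bup,t_b_imp2,t_e_imp2,t_b_imp3,t_R_imp5
1,2.4,37,80,30,8,13,12.53,12.45,12.66,12.71,15.51
2,2.4,43,20,40,8,9,5.89,5.31,5.62,5.55,15.20
3,3.2,40,50,35,6.5,11,9.05,9.03,9.41,9.51,13.29
4,2.4,37,20,40,5,13,8.71,8.67,8.95,9.01,14.07
5,4.0,37,80,30,5,13,10.99,10.89,11.11,11.13,14.27
6,2.4,43,80,40,5,13,6.78,6.71,7.00,7.05,12.38
7,2.4,43,20,30,8,13,5.41,5.32,5.56,5.56,13.84
8,4.0,37,20,40,8,13,9.80,9.83,10.23,10.63,15.24
9,4.0,37,80,40,5,9,9.71,9.55,9.75,9.81,31.50
10,3.2,40,50,35,6.5,11,9.07,9.05,9.34,9.52,13.32
11,2.4,37,80,40,8,9,11.18,10.68,12.52,10.55,33.00
12,2.4,37,20,30,5,9,9.28,9.11,9.29,10.49,32.00
13,2.4,43,80,30,5,9,7.71,7.87,7.97,8.09,32.50
14,4.0,43,20,30,5,13,6.88,6.77,7.01,7.11,12.99
15,4.0,43,20,40,5,9,6.03,5.85,6.11,6.14,11.29
16,3.2,40,50,35,6.5,11,9.01,8.99,9.36,9.51,13.31
17,4.0,37,20,30,8,9,11.11,10.98,11.17,11.17,31.00
18,4.0,43,80,40,8,13,7.10,6.93,7.20,7.25,13.67
19,4.0,43,80,30,8,9,7.86,7.86,8.13,8.32,24.36
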