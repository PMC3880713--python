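run_id,temperature,oil_concentration,inoculum_size,pH,incubation_time,response,predicted,r_student
1,35,12,10,8,4,3.06,2.973,0.479
2,30,14,12,7,4,4.62,4.708,-2.195
3,30,10,12,9,4,3.86,3.862,-0.042
4,30,10,8,7,4,3.74,3.761,-0.437
5,30,14,12,9,2,5.68,5.722,-0.884
6,35,12,10,8,3,3.26,3.528,-1.111
7,35,10,10,8,3,4.92,4.978,-0.318
8,40,14,8,9,2,4.87,4.843,0.561
9,40,14,8,7,4,3.91,3.929,-0.402
10,35,12,10,8,3,3.27,3.522,-1.064
11,35,12,8,8,3,2.90,2.923,-0.128
12,40,10,8,9,4,5.38,5.313,1.509
13,30,12,10,8,3,3.71,3.458,1.533
14,40,10,12,9,2,4.33,4.294,0.748
15,35,12,10,8,3,3.26,3.522,-1.111
16,35,12,10,8,2,3.86,3.522,1.491
17,30,10,8,9,3,4.78,4.754,0.525
18,35,12,10,9,2,4.42,4.520,-0.556
19,30,14,8,7,3,3.16,3.221,-1.351
20,40,12,8,7,2,3.37,3.434,-0.355
21,30,10,10,8,4,3.39,3.442,-1.338
22,40,10,12,7,3,3.19,3.201,-0.224
23,35,14,12,7,4,5.46,5.214,1.484
24,40,14,10,8,2,4.70,4.700,-0.009
25,40,14,12,9,3,3.15,3.200,-1.093
26,35,12,12,7,4,2.93,2.719,1.240
27,30,14,12,8,2,4.56,4.577,-0.219
28,35,12,8,9,3,3.05,2.949,0.561
29,35,12,10,8,3,3.78,3.492,1.815
30,35,12,10,7,3,3.35,3.522,-0.705
31,35,12,10,8,3,3.38,3.522,-0.577
32,35,12,10,8,3,3.35,3.522,-0.705
33,35,12,10,8,3,3.38,3.522,-0.577
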