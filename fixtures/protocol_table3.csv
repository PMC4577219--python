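train,pair_a,pair_b,voltage_V,n_pulses,width_us,rate_Hz,measured_current_A,computed_current_A,phase
1,3,4,2720,20,90,1,26.6,27.4,test
2,1,2,2550,20,90,1,21.5,23.9,test
3,1,3,2380,20,90,1,23.6,25.8,test
4,2,3,2210,20,90,1,21.3,21.0,test
5,4,1,2200,20,90,1,22.5,25.7,test
6,2,4,1650,20,90,1,17.4,16.2,test
7,1,2,3000,70,90,1,30.5,28.4,treatment
8,3,4,2720,70,90,1,30.5,27.4,treatment
9,2,3,2405,70,90,1,30.3,22.8,treatment
10,1,3,2380,70,90,1,30.7,25.9,treatment
11,2,4,2200,70,90,1,31.1,22.3,treatment
12,4,1,2200,70,90,1,29.3,25.6,treatment
13,1,2,2380,20,90,1,24.2,22.1,additional
14,3,4,2380,20,90,1,28.5,23.6,additional
15,1,3,1960,20,90,1,22.1,20.6,additional
16,2,3,1820,20,90,1,20.5,16.8,additional
17,2,4,1540,20,90,1,18.9,14.9,additional
18,4,1,1540,20,90,1,17.2,17.1,additional
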