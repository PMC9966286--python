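run,ethanol,time,temperature,TPC,TFC
1,100,82.5,60,5.41,11.02
2,50,82.5,60,23.69,21.05
3,75,120,70,13.75,12.9
4,50,15,60,10.24,11.52
5,75,120,50,10.21,7.83
6,50,82.5,60,23.12,24.2
7,0,82.5,60,6.53,6.85
8,25,45,70,17.5,11.52
9,25,120,50,8.88,6.81
10,50,82.5,80,23.0,16.05
11,50,82.5,60,23.1,23.59
12,50,82.5,60,23.51,24.01
13,50,82.5,60,23.92,24.01
14,25,45,50,7.85,7.85
15,50,150,60,10.11,9.25
16,75,45,50,11.01,15.25
17,25,120,70,19.22,15.25
18,50,82.5,40,10.05,9.59
19,50,82.5,60,23.1,23.25
20,75,45,70,14.58,12.56
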