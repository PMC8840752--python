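run,P,T,G,selectivity,global_yield
1,250,50,60,1.83,1.76
2,200,60,60,0.57,7.64
3,300,40,60,2.48,2.98
4,200,40,60,2.19,5.11
5,250,50,60,2.11,6.65
6,250,60,150,1.86,4.45
7,300,50,150,0.82,2.51
8,200,50,150,1.96,2.49
9,200,50,42,1.21,4.85
10,300,60,60,0.84,3.26
11,300,50,42,2.35,0.86
12,250,40,42,2.29,1.88
13,250,40,150,1.85,2.92
14,250,50,60,2.17,3.54
15,250,60,42,1.12,2.44
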