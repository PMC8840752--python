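run,P,M,global_yield
1,120,-1,1.25
2,120,1,1.70
3,240,-1,1.71
4,240,1,2.49
5,180,0,2.27
6,180,0,2.33
7,180,0,2.30
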