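depth_cm,dose_density
1,18.39
2,16.11
3,12.50
4,9.31
5,7.16
6,5.75
8,2.79
10,1.40
12,0.69
14,0.43
16,0.15
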