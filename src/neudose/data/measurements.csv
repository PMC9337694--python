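distance_cm,h10_per_gray,sd_per_gray
0,1.30,0.14
20,0.71,0.12
60,0.58,0.10
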