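region,fraction
head,0.131
upper limb-girdle,0.062
sternum,0.034
ribs,0.141
vertebrae,0.109
sacrum,0.139
lower girdle,0.261
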