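organ_name,distance_cm,depth_cm
Brain,5,13.0
Salivary glands,8.38,6.0
Thyroid,15.28,2.0
Esophagus,29.88,13.5
Breast,29.88,2.0
Lung,30.88,12.5
Cord,32.28,16.0
Heart,34.88,9.5
Stomach,43.88,10.5
Spleen,43.88,9.0
Liver,44.38,8.0
Pancreas,45.88,11.0
Kidney,48.88,12.5
Colon,57.88,9.5
Bladder,78.18,8.5
Gonads,79.88,1.0
Rectum,79.38,14.0
Femoral head,83.88,11.5
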