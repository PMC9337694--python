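organ_name,total_mSv,sd_mSv
Bladder,4.20,0.42
Bone marrow,6.00,0.80
Bone surface,9.00,1.20
Breast,37.20,1.16
Esophagus,1.20,0.15
Colon,3.00,0.30
Liver,5.40,0.54
Lung,1.20,0.15
Gonads,34.80,3.50
Skin,38.70,0.22
Stomach,2.40,0.24
Thyroid,37.20,4.00
Rectum,0.60,0.10
Femoral head,1.20,0.20
Salivary glands,13.20,1.70
Spleen,3.60,0.40
Heart,4.20,0.54
Pancreas,2.40,0.30
Kidney,0.60,0.10
Brain,1.20,0.15
Cord,0.60,0.08
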