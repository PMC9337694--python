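organ_name,compartment,w_t,risk_coefficient_1e2_per_sv
Bladder,named,0.05,0.30
Bone marrow,named,0.12,0.50
Bone surface,named,0.01,0.05
Breast,named,0.05,0.20
Esophagus,named,0.05,0.30
Colon,named,0.12,0.85
Liver,named,0.05,0.15
Lung,named,0.12,0.85
Gonads,named,0.20,0.10
Skin,named,0.01,0.02
Stomach,named,0.12,1.10
Thyroid,named,0.05,0.08
Rectum,remainder,,
Femoral head,remainder,,
Salivary glands,remainder,,
Spleen,remainder,,
Heart,remainder,,
Pancreas,remainder,,
Kidney,remainder,,
Brain,remainder,,
Cord,remainder,,
(remainder compartment),scalar,0.05,0.05
(genetic effects),scalar,,1.00
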