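{
  "contributions_mSv": {
    "bladder": 0.21,
    "bone marrow": 0.72,
    "bone surface": 0.09,
    "breast": 1.86,
    "colon": 0.36,
    "esophagus": 0.06,
    "gonads": 6.96,
    "liver": 0.27,
    "lung": 0.14,
    "remainder": 0.15,
    "skin": 0.39,
    "stomach": 0.29,
    "thyroid": 1.86
  },
  "depth_class_mean_per_gray": {
    "deep": 0.02,
    "middle": 0.1,
    "surface": 0.61,
    "unclassified": 0.01
  },
  "effective_dose_mSv": 13.36,
  "genetic_effects_cases_per_million": 348.0,
  "per_organ_risk_cases_per_million": {
    "bladder": 12.6,
    "bone marrow": 30.0,
    "bone surface": 4.5,
    "breast": 74.4,
    "colon": 25.5,
    "esophagus": 3.6,
    "gonads": 34.8,
    "liver": 8.1,
    "lung": 10.2,
    "remainder": 13.8,
    "skin": 7.74,
    "stomach": 26.4,
    "thyroid": 29.76
  },
  "total_risk_cases_per_million": 281.4
}
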