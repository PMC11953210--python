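# Default threshold-derivation config.
#
# Population ids refer to registry.yaml.  Sex offsets are the pooled
# male-minus-female fracture T-score differences: 0.59 for European
# femoral-neck series, 0.62 for the Hong Kong prospective cohorts.
# Adopted male cutpoints: -2.0 for Caucasian men (the "convenience"
# rounding of the raw risk-equivalent -1.91); -2.1 for Chinese men, a
# configured constant adopted from the revised Chinese reference-threshold
# literature (consistent with, but not derived by, the offset arithmetic
# -2.7 + 0.62 = -2.08).
rounding_decimals: 1

groups:
  - ethnicity: US-Caucasian
    site: FN
    female_population: us_older_f
    male_population: us_older_m
    female_cutpoint: -2.5
    sex_offset: 0.59
    adopted_male_cutpoint: -2.0
  - ethnicity: HK-Chinese
    site: FN
    female_population: hk_older_f
    male_population: hk_older_m
    female_cutpoint: -2.7
    sex_offset: 0.62
    adopted_male_cutpoint: -2.1

site_thresholds:
  - site: TH
    cutpoint: -1.7
    status: adopted
    note: "when total hip is reported alone"
  - site: TH
    cutpoint: -2.0
    status: adopted
    note: "when FN and TH are reported together, lower T-score rules"
  - site: LS
    cutpoint: -2.0
    status: working
    note: "tentative working lumbar-spine threshold; evidence limited"
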