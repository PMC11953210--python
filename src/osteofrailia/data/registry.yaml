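# Shipped reference registry: femoral-neck (FN) reference databases and
# older-population Gaussian models used throughout the analyses.
#
# Provenance of numbers:
#   * NHANES III young-adult FN SDs (0.137 M / 0.120 F) and older-population
#     FN BMD SDs (0.139 M / 0.129 F) are the published NHANES III
#     (Looker et al.) values for US non-Hispanic-white adults; the older
#     population is ages >= 50 y.  Young-adult FN mean BMD (0.934 M /
#     0.858 F g/cm2) likewise transcribed from the NHANES III reference
#     tables.
#   * US older-population mean T-scores: -1.241 (men), -1.717 (women).
#   * Hong Kong Chinese young/older FN BMD SDs (young 0.130 M / 0.100 F,
#     older 0.115 M / 0.107 F) from the published Hong Kong reference data;
#     older-population mean FN T-scores -1.25 (men) / -1.76 (women) are the
#     MrOS / MsOS (Hong Kong) baseline means.
#   * Hong Kong young-adult mean BMD values below are SYNTHETIC
#     placeholders (plausible magnitudes, clearly not measured values):
#     the analyses shipped here use the Hong Kong rows only on the T-score
#     scale, but the schema requires a complete young-adult pair.
version: 1

references:
  - id: nhanes3_fn_m
    site: FN
    sex: M
    ethnicity: US-Caucasian
    device_family: Hologic
    young_mean_bmd: 0.934
    young_sd_bmd: 0.137
  - id: nhanes3_fn_f
    site: FN
    sex: F
    ethnicity: US-Caucasian
    device_family: Hologic
    young_mean_bmd: 0.858
    young_sd_bmd: 0.120
  - id: hk_fn_m          # young mean is a synthetic placeholder, see header
    site: FN
    sex: M
    ethnicity: HK-Chinese
    device_family: Hologic
    young_mean_bmd: 0.910
    young_sd_bmd: 0.130
  - id: hk_fn_f          # young mean is a synthetic placeholder, see header
    site: FN
    sex: F
    ethnicity: HK-Chinese
    device_family: Hologic
    young_mean_bmd: 0.820
    young_sd_bmd: 0.100

populations:
  - id: us_older_m
    label: "US Caucasian community men >=50 y (NHANES III)"
    reference: nhanes3_fn_m
    mean_t: -1.241
    sd_bmd: 0.139        # T-score SD = 0.139 / 0.137
  - id: us_older_f
    label: "US Caucasian community women >=50 y (NHANES III)"
    reference: nhanes3_fn_f
    mean_t: -1.717
    sd_bmd: 0.129        # T-score SD = 0.129 / 0.120
  - id: hk_older_m
    label: "Hong Kong Chinese community men >=65 y (MrOS HK baseline)"
    reference: hk_fn_m
    mean_t: -1.25
    sd_bmd: 0.115        # T-score SD = 0.115 / 0.130
  - id: hk_older_f
    label: "Hong Kong Chinese community women >=65 y (MsOS HK baseline)"
    reference: hk_fn_f
    mean_t: -1.76
    sd_bmd: 0.107        # T-score SD = 0.107 / 0.100
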