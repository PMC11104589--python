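# Default synthetic-cohort profile: per-group parameters of the memory-clinic
# study population (135 controls, 108 AD, 33 FTD, 10 VaD).  Rates are exact
# count fractions; continuous features are mean/SD pairs on the published
# scale.  Centiloid is generated conditional on the visual read with
# read-specific normals chosen so the group marginal means match the
# published group means; the read-conditional split itself is a modelling
# choice (only the marginals are published).
groups:
  CN:
    n: 135
    female_rate: 0.42963   # 58/135
    age: {mean: 60.0, sd: 8.0}
    apoe_e4_rate: 0.39259  # 53/135
    pet_positive_rate: 0.20741  # 28/135
    centiloid_negative: {mean: 2.0, sd: 10.0}
    centiloid_positive: {mean: 50.0, sd: 20.0}   # marginal ~ 11.95
    auc_positive_rate: 0.04444  # 6/135
    features:
      mmse: {mean: 28.0, sd: 2.0}
      ravlt_learning: {mean: 39.0, sd: 10.0}
      ravlt_recall: {mean: 8.0, sd: 3.0}
      fluency_animals: {mean: 22.0, sd: 6.0}
      tmt_a: {mean: 39.0, sd: 22.0}
      tmt_b: {mean: 100.0, sd: 65.0}
      npi_total: {mean: 14.0, sd: 16.0}
      cmta_right: {mean: 0.31, sd: 0.51}
      cmta_left: {mean: 0.31, sd: 0.58}
      cgca: {mean: 0.39, sd: 0.58}
      ap_index: {mean: -0.25, sd: 1.23}
      ad_similarity: {mean: 0.47, sd: 0.11}
      wmh_volume: {mean: 6.00, sd: 5.33}
  AD:
    n: 108
    female_rate: 0.51852   # 56/108
    age: {mean: 66.0, sd: 7.0}
    apoe_e4_rate: 0.68519  # 74/108
    pet_positive_rate: 0.95370  # 103/108
    centiloid_negative: {mean: 15.0, sd: 10.0}
    centiloid_positive: {mean: 72.0, sd: 30.0}   # marginal ~ 69.40
    auc_positive_rate: 0.75     # 81/108
    features:
      mmse: {mean: 22.0, sd: 4.0}
      ravlt_learning: {mean: 22.0, sd: 7.0}
      ravlt_recall: {mean: 2.0, sd: 2.0}
      fluency_animals: {mean: 14.0, sd: 5.0}
      tmt_a: {mean: 92.0, sd: 84.0}
      tmt_b: {mean: 294.0, sd: 252.0}
      npi_total: {mean: 9.0, sd: 9.0}
      cmta_right: {mean: 1.37, sd: 0.94}
      cmta_left: {mean: 1.49, sd: 1.07}
      cgca: {mean: 1.52, sd: 0.86}
      ap_index: {mean: 0.03, sd: 1.76}
      ad_similarity: {mean: 0.63, sd: 0.09}
      wmh_volume: {mean: 9.90, sd: 13.1}
  FTD:
    n: 33
    female_rate: 0.39394   # 13/33
    age: {mean: 66.0, sd: 7.0}
    apoe_e4_rate: 0.33333  # 11/33
    pet_positive_rate: 0.06061  # 2/33
    centiloid_negative: {mean: 5.0, sd: 10.0}
    centiloid_positive: {mean: 45.0, sd: 25.0}   # marginal ~ 7.52
    auc_positive_rate: 0.60606  # 20/33
    features:
      mmse: {mean: 24.0, sd: 5.0}
      ravlt_learning: {mean: 26.0, sd: 11.0}
      ravlt_recall: {mean: 4.0, sd: 3.0}
      fluency_animals: {mean: 11.0, sd: 6.0}
      tmt_a: {mean: 70.0, sd: 55.0}
      tmt_b: {mean: 204.0, sd: 171.0}
      npi_total: {mean: 17.0, sd: 15.0}
      cmta_right: {mean: 1.54, sd: 1.20}
      cmta_left: {mean: 1.86, sd: 1.48}
      cgca: {mean: 1.89, sd: 0.95}
      ap_index: {mean: -1.84, sd: 2.79}
      ad_similarity: {mean: 0.57, sd: 0.10}
      wmh_volume: {mean: 11.08, sd: 14.06}
  VaD:
    n: 10
    female_rate: 0.2       # 2/10
    age: {mean: 72.0, sd: 6.0}
    apoe_e4_rate: 0.2      # 2/10
    pet_positive_rate: 0.4 # 4/10
    centiloid_negative: {mean: 2.0, sd: 10.0}
    centiloid_positive: {mean: 37.0, sd: 25.0}   # marginal ~ 15.93
    auc_positive_rate: 0.6 # 6/10
    features:
      mmse: {mean: 24.0, sd: 4.0}
      ravlt_learning: {mean: 23.0, sd: 9.0}
      ravlt_recall: {mean: 3.0, sd: 3.0}
      fluency_animals: {mean: 12.0, sd: 5.0}
      tmt_a: {mean: 70.0, sd: 24.0}
      tmt_b: {mean: 219.0, sd: 69.0}
      npi_total: {mean: 19.0, sd: 21.0}
      cmta_right: {mean: 1.34, sd: 1.10}
      cmta_left: {mean: 1.99, sd: 1.30}
      cgca: {mean: 2.15, sd: 0.81}
      ap_index: {mean: -0.44, sd: 1.53}
      ad_similarity: {mean: 0.61, sd: 0.07}
      wmh_volume: {mean: 21.01, sd: 18.34}
# Missing-completely-at-random rates: published per-feature availability
# (out of 286).  Visual reads were available for everyone.
missingness:
  mmse: 0.01049            # 3/286
  ravlt_learning: 0.03846  # 11/286
  ravlt_recall: 0.03846
  fluency_animals: 0.05944 # 17/286
  tmt_a: 0.04545           # 13/286
  tmt_b: 0.04545
  npi_total: 0.26224       # 75/286
  apoe_e4: 0.01049
  cmta_left: 0.01049
  cmta_right: 0.01049
  cgca: 0.01049
  ap_index: 0.01049
  ad_similarity: 0.01049
  wmh_volume: 0.02448      # 7/286
  centiloid: 0.13287       # 38/286
  pet_visual: 0.0
  age: 0.0
  sex: 0.0
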