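# Baseline parameter set of the urban-China risk-based breast-cancer
# screening programme (2014 US$; annual probabilities).
incidence_by_age:
  40-44: 0.0006100
  45-49: 0.0010056
  50-54: 0.0011650
  55-59: 0.0011179
  60-64: 0.0010458
  65-69: 0.0009782
  70-74: 0.0009912
  75-79: 0.0009067
  80-84: 0.0007803
  85+: 0.0006430
dcis_ratio: 0.12
rr_dcis_to_invasive: 2.02
rr_high_risk: 2.0
comparator_high_risk: true
progression:
  stage_i_to_ii: 0.06
  stage_ii_to_iii: 0.11
  stage_iii_to_iv: 0.15
  stage_iv_to_death: 0.23
symptom_prob:
  stage_i: 0.004
  stage_ii: 0.014
  stage_iii: 0.380
  stage_iv: 0.980
fatality_treated:
  stage_i: 0.006
  stage_ii: 0.042
  stage_iii: 0.093
  stage_iv: 0.275
test_perf:
  ultrasound_then_mammography:
    sensitivity: {baseline: 0.848, min: 0.681, max: 0.949}
    specificity: {baseline: 0.994, min: 0.990, max: 0.996}
  ultrasound_plus_mammography:
    sensitivity: {baseline: 0.939, min: 0.798, max: 0.993}
    specificity: {baseline: 0.980, min: 0.975, max: 0.985}
utility:
  stage_i: {baseline: 0.79, min: 0.77, max: 0.80}
  stage_ii: {baseline: 0.79, min: 0.78, max: 0.80}
  stage_iii: {baseline: 0.77, min: 0.76, max: 0.79}
  stage_iv: {baseline: 0.69, min: 0.65, max: 0.72}
disutility_fp: {baseline: 0.25, min: 0.11, max: 0.34}
# duration of the false-positive disutility episode (positive screen to
# biopsy resolution), in years
fp_disutility_duration_years: 0.09615384615384616
costs:
  questionnaire: {baseline: 1.6, min: 1.1, max: 2.1}
  screening: {baseline: 85.5, min: 59.8, max: 111.1}
  biopsy: {baseline: 45.6, min: 31.0, max: 59.3}
  treatment:
    dcis: {baseline: 2435, min: 1705, max: 3166}
    stage_i: {baseline: 10067, min: 7047, max: 13087}
    stage_ii: {baseline: 11068, min: 7748, max: 14388}
    stage_iii: {baseline: 12867, min: 9007, max: 16727}
    stage_iv: {baseline: 17766, min: 12436, max: 23096}
discount_rate: 0.03
wtp_threshold: 23050
preclinical_stage_utility: true
half_cycle_correction: false
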