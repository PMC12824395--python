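# Example pipeline configuration for `medseq run --config`.
# Every key is optional; omitted keys use the documented defaults.
out_dir: medseq_out
grace_days: 30
window: 3
cval: 2.0
indel: 1.0
k_min: 2
k_max: 15
methods: [pam, ward_then_pam, ward]
adjust_factors:
  [population_group, sex, age_group, education, living_with_partner, prior_depression]
generator:
  n_persons: 6000
  seed: 1
  state_noise_prob: 0.05
  hospitalization_rate: 0.05
  death_rate: 0.01
  prior_bd_rate: 0.02
  washout_med_rate: 0.02
  psychosis_rate: 0.01
  group_proportions: [0.828, 0.076, 0.059, 0.036]
  typology_logit_coefficients:
    - factor: population_group
      level: refugee
      coefficients: [0, -0.9, -0.9, -0.9, -0.9, -0.9, -0.9]
    - factor: population_group
      level: non_refugee
      coefficients: [0, -0.55, -0.55, -0.55, -0.55, -0.55, -0.55]
    - factor: population_group
      level: second_gen
      coefficients: [0, -0.45, -0.45, -0.45, -0.45, -0.45, -0.45]
    - factor: education
      level: low
      coefficients: [0, -0.3, -0.3, -0.3, -0.3, -0.3, -0.3]
    - factor: education
      level: high
      coefficients: [0, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25]
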