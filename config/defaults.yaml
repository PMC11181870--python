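# Default pipeline configuration: analysis constants at their standard values
# (30% detection frequency, nominal p < .05, concordance in >= 3 of 4 eGFR
# equations, Spearman p < .1, SVM C = 256 / gamma = 2e-5, model developed on
# the EKFC cystatin labeling). The simulation block generates a cohort at
# a realistic discovery scale when no input files are given.
outdir: nephropep_run
seed: 0
visits_path: null
matrix_path: null
standards_path: null
methods: [CKD_EPI_CR, CKD_EPI_CYS, CKD_EPI_CR_CYS, EKFC_CYS]
window: full_period
rule_set: discovery
validation_cohort_rule: loss_lt_10
training_method: EKFC_CYS
frequency_threshold: 0.30
p_threshold: 0.05
min_methods: 3
rho_p_threshold: 0.1
svm_c: 256.0
svm_gamma: 2.0e-05
run_take_one_out: true
simulation:
  n_patients: 200
  n_visits: 4
  visit_interval_mean: 1.0
  visit_interval_sd: 0.2
  n_peptides: 2000
  n_differential: 200
  effect_size: 1.0
  frac_down: 0.8
  decline_frac: 0.5
  true_decline_rate: -15.0
  true_stable_rate: 0.0
  measurement_cv_creatinine: 0.05
  measurement_cv_cystatin: 0.05
  detection_base_freq: 0.7
  seed: 0
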