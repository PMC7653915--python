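# Full study matrix: educational attainment (EA) and cognitive performance
# (CP) on suicide-attempt risk, with household-income, alcohol, smoking and
# mental-health-consultation co-exposures, against the two suicide-attempt
# GWAS models (model 1: unadjusted; model 2: adjusted for comorbid mental
# disorders).
#
# The dataset paths are placeholders for the publicly downloadable summary
# statistics (SSGAC, IEU Open GWAS, iPSYCH); download them, fix the paths,
# and run:
#
#   summr study --config configs/full_study.yaml --out-dir study_out
#
# Column-map presets are best-effort defaults per portal; override with an
# explicit mapping if your download's headers differ.
seed: 20200918
datasets:
  education:
    path: data/ssgac_ea3_excl_23andme.txt.gz
    column_map: ssgac
    trait_type: continuous
    unit: SD of years of schooling (4.2 years)
  cognitive_performance:
    path: data/ssgac_cp_cogent_ukb.txt.gz
    column_map: ssgac
    trait_type: continuous
    unit: SD of standardized score
  household_income:
    path: data/ieu_ukb_b_7408_income.txt.gz
    column_map: ieu
    trait_type: continuous
    unit: ordered income category
  alcohol_consumption:
    path: data/ssgac_alcohol_units_weekly.txt.gz
    column_map: ssgac
    trait_type: continuous
    unit: alcohol units per week
  ever_smoker:
    path: data/ieu_ukb_b_20160_ever_smoker.txt.gz
    column_map: ieu
    trait_type: binary
    unit: log-odds of ever smoking
  seen_gp:
    path: data/ieu_ukb_b_2090_seen_gp.txt.gz
    column_map: ieu
    trait_type: binary
    unit: log-odds of ever seeing a GP for nerves/anxiety/depression
  seen_psychiatrist:
    path: data/ieu_ukb_b_2100_seen_psychiatrist.txt.gz
    column_map: ieu
    trait_type: binary
    unit: log-odds of ever seeing a psychiatrist
  suicide_attempt_model1:
    path: data/ipsych_suicide_attempt_model1.txt.gz
    column_map: ipsych
    trait_type: binary
    unit: log-odds of hospital-recorded suicide attempt
  suicide_attempt_model2:
    path: data/ipsych_suicide_attempt_model2.txt.gz
    column_map: ipsych
    trait_type: binary
    unit: log-odds, adjusted for comorbid mental disorders
analyses:
  # --- single-variable total effects, both outcome models ---
  - {kind: svmr, exposures: [education], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [cognitive_performance], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [household_income], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [alcohol_consumption], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [ever_smoker], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [seen_gp], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [seen_psychiatrist], outcome: suicide_attempt_model1}
  - {kind: svmr, exposures: [education], outcome: suicide_attempt_model2}
  - {kind: svmr, exposures: [cognitive_performance], outcome: suicide_attempt_model2}
  - {kind: svmr, exposures: [household_income], outcome: suicide_attempt_model2}
  # --- reverse direction: does suicide attempt affect EA or CP? ---
  - {kind: bidirectional, exposures: [education], outcome: suicide_attempt_model1}
  - {kind: bidirectional, exposures: [cognitive_performance], outcome: suicide_attempt_model1}
  # --- multivariable direct effects ---
  - {kind: mvmr, exposures: [education, cognitive_performance],
     outcome: suicide_attempt_model1}
  - {kind: mvmr, exposures: [education, cognitive_performance],
     outcome: suicide_attempt_model2}
  - {kind: mvmr, exposures: [education, cognitive_performance, household_income],
     outcome: suicide_attempt_model1}
  - {kind: mvmr, exposures: [education, cognitive_performance, household_income],
     outcome: suicide_attempt_model2}
  - {kind: mvmr, exposures: [education, alcohol_consumption, ever_smoker],
     outcome: suicide_attempt_model1}
  - {kind: mvmr, exposures: [education, alcohol_consumption, ever_smoker, seen_gp],
     outcome: suicide_attempt_model1}
  - {kind: mvmr, exposures: [education, alcohol_consumption, ever_smoker, seen_psychiatrist],
     outcome: suicide_attempt_model1}
thresholds:
  gws_p: 5.0e-8
  clump_r2: 0.001
  clump_window_kb: 10000
  palindrome_af_window: [0.42, 0.58]
  presso_outlier_p: 0.10
  presso_global_flag_p: 0.01
  egger_intercept_flag_p: 0.01
  steiger_p: 0.01
  alpha: 0.025
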