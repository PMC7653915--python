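# Synthetic demonstration study.
#
# Generate the input files first (from the directory holding this config):
#
#   summr simulate --m-snps 224 --theta -0.646 --seed 7 --out-dir demo_data
#
# then run:
#
#   summr study --config configs/synthetic_demo.yaml --out-dir demo_out
seed: 7
datasets:
  education:
    path: demo_data/exposure.tsv
    trait_type: continuous
    unit: SD of years of schooling
  suicide_attempt:
    path: demo_data/outcome.tsv
    trait_type: binary
    unit: log-odds
analyses:
  - kind: svmr
    exposures: [education]
    outcome: suicide_attempt
  - kind: bidirectional
    exposures: [education]
    outcome: suicide_attempt
thresholds:
  presso_n_sim: 1000
  n_boot: 1000
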