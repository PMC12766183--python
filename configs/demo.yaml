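# Packaged demo: synthetic cohort with 2 shared + 2 male-only + 2 female-only
# informative proteins among 60, run end to end.
#   proteorisk run-all --config configs/demo.yaml --out runs/demo --seed 1
out_dir: runs/demo
seed: 1
simulate:
  n_participants: 6000
  male_fraction: 0.5
  n_proteins: 60
  protein_block_size: 5
  protein_block_correlation: 0.3
  informative_male:
    1: 0.693   # shared, ln 2
    2: 0.588   # shared, ln 1.8
    6: 0.693   # male-only
    7: 0.588   # male-only
  informative_female:
    1: 0.693
    2: 0.588
    11: 0.693  # female-only
    12: 0.588  # female-only
  baseline_hazard_rate: 0.008
  dropout_rate: 0.005
  missing_rate_range: [0.0, 0.05]
  lod_quantile_range: [0.0, 0.05]
preprocess:
  max_missing_protein: 0.20
  max_lod: 0.25
  max_missing_participant: 0.50
  derivation_fraction: 0.70
  impute_estimator: ridge   # fast chained-equations variant; 'forest' = default
  impute_iterations: 5
selection:
  n_bootstrap: 40
  n_folds: 10
  frequency_threshold: 0.95
  n_lambda: 10
  lambda_decades: 1.5
  cv_rule: 1se
evaluation:
  cuts: [0.05, 0.10]
  n_bootstrap_ci: 1000
  status_method: km
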