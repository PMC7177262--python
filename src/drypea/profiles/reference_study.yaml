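# Default "reference" study conditions: three connected RIL families from
# three founders, ~600 markers on 7 chromosomes, GBS-like missingness, and
# three drought-stress environments with the calibrated GE structure.
profile:
  n_chromosomes: 7
  chromosome_length_cm: 120.0
  markers_per_chromosome: 100
  founder_ids: [A, I, K]
  crosses: [[A, I], [K, A], [K, I]]
  family_sizes: [96, 92, 100]
  n_selfing: 4
  mean_missing_rate: 0.15
  genotyping_error_rate: 0.0
  environments: [ms, severe, moderate]
  severe_environments: [ms, severe]
  env_means: [0.32, 0.36, 1.38]
  replications: [4, 3, 3]
  h2_targets: [0.87, 0.475, 0.522]
  effect_scale: 1.0
maf_min: 0.025
missing_max: 0.2
knn_k: 4
models: [rrblup, bayesian_lasso]
cv_folds: 10
cv_reps_rrblup: 5
cv_reps_bl: 2
holdout_per_population: 30
n_selected: 3
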