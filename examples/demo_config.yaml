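# Desk-scale demonstration pipeline: simulate a three-profile cohort,
# screen dimensionality, fit candidate models, compare, and run the
# covariate-adjustment ladder for the DQI coefficient.
#
#   mgrlmm run --config examples/demo_config.yaml
#
output_dir: scratch/demo_run
seed: 1
simulate:
  n_subjects: 300
  n_dims: 3
efa:
  wave: 1
candidates: [2, 3]
sampler:
  chains: 4
  warmup: 1000
  draws: 1000
fit_covariates: [dqi, age, sex]
ladder_models: [1, 2, 3, 4, 5]
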