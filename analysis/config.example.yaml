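# Example pipeline configuration for `camwm run-all --config ...`
# Stage and sampler settings mirror the analysis/ scripts; any field of
# RunConfig (and the nested configs) can be overridden here.
out_dir: results/run
seed: 1
stages: [simulate, prep, cam, associate, power, report]

cohort:
  n_studies: 6
  participants_per_study: [25, 25, 25, 30, 25, 25]
  trials_per_participant: 60
  latent_corr: 0.66
  nu_true: 8.0
  outlier_rate: 0.02

filters:
  max_abs_angular_error: 45.0
  amplitude_ratio_range: [0.5, 1.75]
  quadrant_rule: true

power:
  sizes: [15, 45, 75, 105, 155]
  n_resamples: 60

power_network: frontoparietal
power_phase: delay
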