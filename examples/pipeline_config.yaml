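# Reference pipeline configuration: the study-mimicking defaults.
# Every value shown equals the built-in default; override as needed and
# pass with `radiotme run-full --config pipeline_config.yaml ...`.

out_dir: pipeline_out
bits: 8                     # rescale in-mask intensities to 8 bits
bin_width: 25.0             # fixed-bin-width gray-level quantization
kinetic_levels: 11          # bins for the kinetic parameter maps
adjust_within_population: false   # BH family = all 1990 pair tests jointly
candidate_sizes: [2, 3, 4, 6, 8, 10, 12, 16, 20]
hyperparams:
  n_estimators: 100
  max_depth: 3
  learning_rate: 0.1
nested_selection: false     # true nests RFE inside every LOOCV fold
rfe_cv_folds: 5
rfe_cv_repeats: 5
seed: 0
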