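# Small end-to-end demo: simulate a panel, QC it, estimate H2 per trait x
# regime, and evaluate ridge + random forest under 30-iteration KFCV.
seed: 7
output_dir: results/demo
simulate:
  n_lines: 100
  n_markers: 1000
  missing_rate: 0.03
  het_rate: 0.01
  traits:
    TKW:
      target_h2: 0.69
      mu: 37.77
      effect_model: point_mass_mixture
      pi_zero: 0.95
    GY:
      target_h2: 0.20
      mu: 6.39
qc:
  maf_threshold: 0.05
  max_missing: 0.30
  knn_k: 5
models: [rrblup, rf, xgb]
model_params:
  rf:
    grid: {max_depth: [40], max_features: [sqrt], n_estimators: [150]}
  xgb:
    grid: {max_depth: [4], learning_rate: [0.1], n_estimators: [150]}
schemes:
  - kind: kfcv
    n_iterations: 30
  - kind: cross_condition
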