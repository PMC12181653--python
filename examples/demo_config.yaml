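# 10-node demonstration pipeline: simulate a two-wave panel from a sparse
# known truth network, then run screening, network estimation, centrality
# and stability end to end.  `clpnet all --config examples/demo_config.yaml`
seed: 1
output_dir: demo_out
simulation:
  nodes: 10
  n: 2000
  edge_density: 0.089      # 8 directed cross-lagged edges
  effect_size: 0.4
  autoregression: 0.3
  within_wave_corr: 0.3
  truth_seed: 7
estimator:
  n_folds: 10
  lambda_rule: 1se
bootstrap:
  n_boot: 200
  case_n_boot: 50
display_threshold: 0.05
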