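# Run configuration for the 5-state harmonic benchmark.
# Every key is optional; the values below are the defaults.
#
#   edsflow run-all --config examples/benchmark.yaml --seed 1 --out-dir reeds_run

system:
  preset: benchmark        # benchmark | bottleneck | random
thermo:
  temperature: 300.0
exploration:
  n_initial_s: 21          # log-spaced between 1 and s_min
  s_min: 1.0e-5
  undersampling_occurrence_min: 0.75
  levels_below: 2
  bias_offset_magnitude: 500.0
  state_opt_tail_fraction: 0.30
  peoe_undersampling_min: 0.9
  threshold_quantile: 0.95
  lower_bound_steps: 4000
  state_opt_steps: 4000
  peoe_steps: 8000
  peoe_n_replicas: 12
optimization:
  s_iteration_steps: [3000, 6000, 9000]
  max_s_iterations: 6
  n_insert: 4
  rebalance_steps: 5000
  max_rebalance_iterations: 20
  f_mc_tolerance: 0.12
  rt_time_limit_ns: 0.5
  steps_per_ns: 5.0e5
production:
  n_steps: 40000
  exchange_interval: 20
  record_interval: 1
rebalance_intensity_factor: 30.0
start_mode: SSM            # SSM | 1SS
seed: 1
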