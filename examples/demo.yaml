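cytometry:
  n_events: 10000
  pi_quantile: 0.995
  planted_pi_fraction: 0.3
  syto_quantile: 0.005
inputs: {}
kinetics:
  kill:
    f_sensitive: 0.99
    k_fast: 2.0
    k_slow: 0.05
    n0: 1.0
    n_points: 15
    noise_cv: 0.05
    t_max_days: 14.0
  lag:
    dt_hours: 4.0
    growth_rate: 0.05
    lag_days: 3.0
    min_rate: 0.01
    n_boot: 500
    noise_cv: 0.05
    od0: 0.05
    span_days: 8.0
msd:
  normalize_to_reference: false
  q_unit: invA
  q_window:
  - 0.3
  - 1.5
reduce:
  transmission: 0.9
resilience:
  method: analytic_propagation
  n_boot: 1000
respiration:
  basal_rate: 1.0
  duration_min: 60.0
  noise_sd: 0.0
  o2_0: 200.0
  recovered_rate: 0.9
  stressed_rate: 0.25
seed: 1
simulate:
  enabled: true
  noise: true
  scenarios:
    control:
      populations:
      - - 1.0
        - 0.35
        - 0.4
    recovered:
      populations:
      - - 1.0
        - 0.35
        - 0.4
    stressed:
      populations:
      - - 0.5
        - 0.35
        - 0.4
      - - 0.5
        - 0.1
        - 1.2
stages:
- simulate
- reduce
- msd
- resilience
- kinetics
- cytometry
- respiration
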