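# Seeded synthetic datasets emulating a 70 degC stress test paired with
# 8 degC storage, a Stern-Volmer quench ladder, and TEM cluster areas.
seed: 1
out_dir: sim
kinetics:
  channel: fe_supernatant_ug_per_ml
  initial_value: 12.0          # ug/mL supernatant iron
  slope1: -0.0771              # ug/mL/min, first (decrease) stage
  breakpoint_min: 60.0
  slope2: 0.03                 # ug/mL/min, second (increase) stage
  noise_sd: 0.24               # ~2 % of the initial value
  timepoints_min: [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120]
  A: 3.15                      # generating temperature coefficient
  T_ref_C: 70
  T_target_C: 8
  protein: HSA
  protein_mg_per_ml: 0.5
  pH: 7.4
quench:
  k: 3.97                      # 1/uM -> C50 at the top of the ladder
  F0: 100.0
  q_grid: [0, 0.028, 0.056, 0.084, 0.112, 0.14, 0.168, 0.196, 0.224, 0.252]
  noise_sd: 0.02
  protein: HSA
  temperatures_C: [25, 36]
  pH: 7.4
turbidity:
  tau: 0.65                    # per path-length unit
  path_length: 1.0
  timepoints_min: [0, 1440, 2880, 4320, 5760, 7200]
  drift_per_min: 0.0
  noise_sd: 0.005
areas:
  - {label: no_HSA, n: 70, median_nm2: 738.5, sigma_log: 0.7}
  - {label: with_HSA, n: 70, median_nm2: 2422.1, sigma_log: 0.7}
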