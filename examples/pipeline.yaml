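# Full shelf-life pipeline over the CSVs written by `nanoshelf simulate
# --config examples/simulate.yaml`.
stress_csv: sim/stress.csv
storage_csv: sim/storage.csv
channel_rules:
  - channel: fe_supernatant_ug_per_ml
    percent: 25
    direction: decrease
target_temperatures_C: [8, 25, 37]
A_initial: 2.5
A_bounds: [1.5, 6.0]
A_tol: 1.0e-6
diagnostic_grid: [2.5, 2.6, 2.8, 3.0, 3.15]
seed: 1
out_dir: report
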