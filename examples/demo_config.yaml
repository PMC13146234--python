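# A scaled-down demo day: flat arrivals, adult crowd, fast to simulate.
schema_version: 1
seed: 7
gap_threshold_s: 600
max_dwell_min: 6.0
scenario:
  date: 2023-10-28
  smoker_rate_per_hour:  [0,0,0,0,0,0,0,0,0,0, 40,40,40,40,40,40,40,40,40,40,40,0, 0,0]
  passerby_rate_per_hour: [0,0,0,0,0,0,0,0,0,0, 100,100,100,100,100,100,100,100,100,100,100,0, 0,0]
  smoker_carriage_p: 0.5
  passerby_carriage_p: 0.3
validation:
  start: "15:00:00"
  end: "15:30:00"
rf:
  n_estimators: 10
  max_depth: 5
  min_samples_split: 2
  cv_folds: 5
  test_fraction: 0.4
  seed: 7
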