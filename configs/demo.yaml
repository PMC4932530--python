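# Demo run: 200x200 island landscape with a continental strip, three
# virtual cloud-belt endemics, two 2070-style scenarios.
seed: 42
landscape:
  n_rows: 200
  n_cols: 200
  n_islands: 6
  n_archipelagos: 3
  sea_level: 50.0
  n_continent_cols: 30
variables: default
species: default
scenarios: default
n_presences: 60
n_background: 1000
pa_fraction: 0.3
reps: 10
split: 0.7
n_trees: 100
thresholds:
  r_max: 0.8
  min_records: 11
  auc_min: 0.8
  tss_min: 0.7
  error_rate: 0.05
  pa_overlap: 0.05
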