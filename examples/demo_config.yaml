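# Shipped 50x50 two-species demo: rangecast run-all --config examples/demo_config.yaml
nrows: 50
ncols: 50
cellsize: 1000.0
impervious_fraction: 0.05
species:
- name: wide_niche
  role: generalist
  n_presences: 60
  elevation_cutoff: null
  rappel_weight: null
  ldd_probability: null
  occurrences_csv: null
- name: narrow_niche
  role: specialist
  n_presences: 60
  elevation_cutoff: null
  rappel_weight: null
  ldd_probability: null
  occurrences_csv: null
scenario_name: warming_trend
periods:
- label: current
- label: '2050'
  shifts:
    temperature: 1.5
    max_temperature: 1.5
- label: '2070'
  shifts:
    temperature: 2.5
    max_temperature: 2.5
ensemble:
  n_pa_replicates: 2
  pa_counts:
    boosted_trees: 300
    additive_model: n_presence
    maxent_like: 300
dispersal:
  replicates: 10
  steps_per_period:
    current: 0
    '2050': 15
    '2070': 10
connectivity_c: 8.0
master_seed: 1
output_dir: demo_out
run_dispcs: true
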