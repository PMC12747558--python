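# hydroscreen run configuration (defaults; every threshold is auditable here)
output_dir: hydroscreen_run
seed: 0

synthetic:
  n_mags: 281
  completeness_range: [70.0, 100.0]
  contamination_range: [0.0, 10.0]
  enzyme_prevalence: {FDH: 0.30, AK: 0.50, BK: 0.33}
  archaea_fraction: 0.021
  n_carbons: 53
  n_supplements: 5
  single_carbon_fraction: 0.93
  auxotroph_fraction: 0.25

# used when the generate stage is disabled
mags_path: null

screening:
  min_completeness: 70.0        # pass iff strictly greater
  max_contamination: 10.0       # pass iff strictly below
  hq_min_completeness: 90.0     # high-quality tier; set 95 for the stricter call
  hq_max_contamination: 5.0
  triad_rule: any               # any | all

fba:
  growth_threshold: 1.0e-6
  default_uptake: 10.0
  anaerobic: true

spectrum:
  max_k: 3

model_format: native

stages:
  generate: true
  screen: true
  build_models: true
  spectrum: true
  design: true
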