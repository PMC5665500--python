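# Example full-pipeline configuration for `muacprobit run --config run_config.yaml`.
# Paths are resolved relative to this file's directory.

seed: 1            # master seed; mandatory, fans out into per-stage substreams
out_dir: out       # results.csv, metrics.csv, classification.csv, manifest.json

# Synthetic source populations. Any PopulationSpec field may be set;
# omitted fields use the defaults (40 clusters x 20 children, SD 12.5 mm,
# ICC 0.05, region east_africa, clustered design).
populations:
  - {muac_mean_mm: 128.0, region: east_africa, livelihood: pastoral}
  - {muac_mean_mm: 134.0, region: east_africa}
  - {muac_mean_mm: 140.0, region: asia, residence: urban}
  - {muac_mean_mm: 144.0, region: asia, date_period: before_2006}
  - {muac_mean_mm: 148.0, region: west_africa, design: simple_random}

# Alternatively (or additionally) child-level CSVs with columns
# survey_id, cluster_id, muac_mm, region, livelihood, residence, design,
# date_period — they are cleaned with `cleaning_bounds` and must have
# >= 25 clusters if clustered:
# population_csvs: [surveys/s001.csv, surveys/s002.csv]

cleaning_bounds: [80.0, 220.0]   # plausibility range for MUAC (mm)

design:
  sample_sizes: [25, 50, 75, 100, 125, 150, 175, 200]
  reps: 100            # simulated surveys per (population, size)
  n_clusters_sub: 25   # clusters drawn per simulated cluster survey

estimators:
  methods: [classic, probit_I, probit_II]
  cutoffs: [115.0, 125.0]   # SAM / GAM case-defining MUAC cutoffs (mm)
  n_boot: 2000              # bootstrap replications per confidence interval

# SD reference for PROBIT Method I. source: builtin (shipped regional means),
# build (from prior-survey CSVs), or file (a previously saved sdref.json).
sd_reference:
  source: builtin
  dispersion_mm: 0.0    # >0 spreads the built-in point masses
  # source: build
  # survey_csvs: [prior/p001.csv, prior/p002.csv]
  # n_boot: 2000
  # source: file
  # path: sdref.json

thresholds_pct: [5, 10, 15]   # GAM decision thresholds for classification
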