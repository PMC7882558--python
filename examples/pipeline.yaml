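# Full pipeline on a synthetic dataset generated in-run.
# For field data, replace `generate` with:
#   inputs:
#     counts: data/counts.csv
#     nests: data/nests.csv
#     climate: data/climate.csv
seed: 11
generate: true
generate_options:
  n_years: 77
  nests_per_year_mean: 85.0
  realism_mode: gaussian

scan:
  enabled: true
  max_lag: 12
  reference_month: 6

# The scan only ranks windows. The structural stages use the windows named
# here; with synthetic data the generator attaches the true-window aggregates
# to the series, so this block documents the selection that would be required
# for field data.
windows:
  auto_select: false
  selected:
    med_winter_temp:   {site: mediterranean,      variable: temp,   open_lag: 6, close_lag: 5}
    eur_spring_precip: {site: europe,             variable: precip, open_lag: 5, close_lag: 2}
    afr_autumn_precip: {site: africa_nonbreeding, variable: precip, open_lag: 9, close_lag: 8}
    eur_winter_temp:   {site: europe,             variable: temp,   open_lag: 4, close_lag: 4}
    afr_winter_temp:   {site: africa_nonbreeding, variable: temp,   open_lag: 7, close_lag: 7}

rdsem:
  chains: 2
  draws: 800
  ar_candidates: [1, 2, 3]

msem:
  chains: 2
  draws: 600
  slope_percentiles: [10, 25, 50, 75, 90]
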