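# Example pipeline configuration (all keys optional; defaults shown in
# dendrorecon.pipeline.DEFAULT_CONFIG). Exactly one of the simulate block
# or input paths must be active.
seed: 1

simulate:
  enabled: true
  n_years: 719
  first_year: 1300
  r_target: 0.73          # chronology-vs-precipitation calibration target
  cycles: [[2.7, 0.35], [8.2, 0.35]]   # (period yr, amplitude x interannual SD)
  n_sites: 3
  trees_per_site: 8

# To run on real data instead, disable simulate and point at files:
# simulate: {enabled: false}
# inputs:
#   rwl: [site1.rwl, site2.rwl]
#   climate: {path: station.csv, layout: wide, variable: prcp}

detrend:
  prewhiten: true         # residual chronology feeds the reconstruction
  max_ar_order: 3
  fallback: mean          # or "line"

eps:
  threshold: 0.85
  window: 50
  overlap: 25
  min_overlap: 30

season:
  variable: prcp
  months: [2, 3, 4, 5, 6] # Feb-Jun
  aggregation: sum

calibration:
  start: 1965
  end: 2018
  split_year: null        # default: median calibration year

response:
  enabled: true
  nboot: 200
  seascorr_nsim: 200

spectral:
  nw: 2.0
  k_tapers: 3

extremes:
  k_years: 1.5            # extreme-year threshold, SD units
  k_periods: 1.0          # wet/dry-period threshold on the low-pass, SD units
  cutoff: 10              # low-pass 50% response wavelength, yr
  min_len: 2
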