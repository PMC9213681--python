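# Default agrochill pipeline configuration.
# Every analysis constant is explicit here: event definitions (frost < -1 degC
# for >= 3 h; abnormal heat > 25 degC for >= 3 h), analysis week ranges
# (frost 2-10, abnormal heat 49-8), QC thresholds, warming-scenario offsets,
# the 11-member GCM ensemble, and IDW interpolation parameters.
archetypes: null
events:
  frost_min_hours: 3
  frost_threshold_c: -1.0
  frost_weeks:
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
  - 8
  - 9
  - 10
  heat_min_hours: 3
  heat_threshold_c: 25.0
  heat_weeks:
  - 49
  - 50
  - 51
  - 52
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
  - 8
  probability_cutoff: 0.1
idw:
  cell_deg: 0.05
  mask_km: 50.0
  power: 2.0
network:
  archetype_mix:
  - 0.3333333333333333
  - 0.3333333333333333
  - 0.3333333333333333
  bbox:
  - 36.5
  - 42.5
  - -6.5
  - 1.5
  climate_jitter: 0.5
  n_stations: 12
  seed: 42
  years:
  - 2000
  - 2020
qc:
  min_fraction: 0.9
  min_years: 5
scenarios:
  ensemble_size: 11
  gcm_spread_sd: 0.3
  gcms:
  - bcc-csm1-1-m
  - BNU-ESM
  - CanESM2
  - CMCC-CM
  - GFDL-ESM2G
  - inmcm4
  - IPSL-CM5A-LR
  - MIROC-ESM
  - MPI-ESM-LR
  - MPI-ESM-MR
  - MRI-CGCM3
  list:
  - - '2035'
    - RCP4.5
  - - '2035'
    - RCP8.5
  - - '2055'
    - RCP4.5
  - - '2055'
    - RCP8.5
  offsets:
    2035_RCP4.5: 1.0
    2035_RCP8.5: 1.4
    2055_RCP4.5: 1.8
    2055_RCP8.5: 2.5
  seed: 7
  statistic: mean
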