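# Desk-scale end-to-end pipeline configuration.
# Run with:  dynexposure run examples/config.yaml
# The simulate stage writes all inputs into output_dir; the later stages
# consume them from there exactly as they would consume real files.
output_dir: scratch/demo_run
seed: 7
simulate: true
log_level: INFO

scenario:
  extent: [114.0, 30.3, 114.5, 30.8]
  n_taxis: 10
  n_days: 3
  sampling_interval_s: 10
  gps_noise_sigma_m: 10.0
  # episode peaking near 300 ug/m3 on days 1-2 of the window
  episode: {start_day: 1, duration_days: 1.5, peak: 300.0}

preprocess:
  sigma_m: 10.0
  beta_m: 200.0
  candidate_radius_m: 50.0
  max_speed_kmh: 120.0

field:
  z_threshold: 5.0
  # override_station: ST04   # uncomment to pin the representative station

exposure:
  lambda_filtration: 1.0
  # the study rule (>=10 weekdays or >=4 weekend days) scaled to 3 days:
  min_weekdays: 2
  min_weekend_days: 1
  extreme_fraction: 0.1

kde:
  cell_size: 0.001
  bandwidth: 0.005
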