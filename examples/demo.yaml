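# Demo pipeline configuration: small simulated cohort, full analysis.
#   mnexcite run --config examples/demo.yaml --out out/
seed: 42

simulate:
  group_sizes:
    sarcopenic: 3
    control: 3
    athlete: 3
  intensities: [0.2, 0.4, 0.6]
  n_trials: 1
  pool:
    n_units: 30
    isi_cv: 0.1

analysis:
  pnr_min_db: 30.0
  torque_lowpass_hz: 15.0

stats:
  enabled: true
  bootstrap_B: 500
  outcomes: [delta_f_pps, brace_pct_rtri, peak_dr_pps]
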