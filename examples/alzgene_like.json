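{
  "seed": 2026,
  "n_markers": 100,
  "studies_range": [4, 30],
  "nonnull_fraction": 0.1,
  "effect_range": [0.1, 0.5],
  "tau2_range": [0.0, 0.04],
  "sigma_range": [0.08, 0.4],
  "start_year": 1995,
  "year_gap_mean": 0.7,
  "model": "proteus",
  "log_weights": [-0.8, -0.1, -0.5, -0.2]
}
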