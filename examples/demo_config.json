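{
  "seed": 42,
  "stages": ["simulate", "dec-summarize", "diversify", "pd", "hapnet"],
  "simulate": {
    "n_tips": 18,
    "crown_age": 14.0,
    "rates": [0.04, 0.29],
    "shift_ages": [7.82],
    "n_posterior_trees": 200
  },
  "dec": {
    "params_mode": "fixed",
    "congruence_threshold": 0.95
  },
  "diversify": {
    "delta_aic": 4.0,
    "models": ["yule1", "bd", "yule2", "yule3"],
    "include_stem": true
  },
  "pd": {
    "reps": 1000
  },
  "hapnet": {
    "prob": 0.95
  }
}
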