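{
  "n_lines_retained": 7,
  "excluded_lines": [
    "B_L4"
  ],
  "tradeoff_slope": 1.5,
  "deviation_slope": 1.5,
  "mass_residualized_slope": 1.5,
  "population_means": {
    "A": {
      "persistence_fraction": 0.3333333333333333,
      "mean_sqrt_emergence": 2.5
    },
    "B": {
      "persistence_fraction": 0.3333333333333333,
      "mean_sqrt_emergence": 3.5
    }
  },
  "front_ids": [
    "A"
  ],
  "dominated_by": {
    "B": "A"
  },
  "perm_historical": {
    "p_value": 0.5,
    "tail": "lower",
    "method": "exact"
  },
  "perm_deviation": {
    "p_value": 1.0,
    "tail": "two_sided"
  },
  "line_summaries": {
    "A_L1": {
      "persistence_fraction": 0.0,
      "mean_sqrt_emergence": 2.0,
      "viable_fraction": 0.75
    },
    "A_L2": {
      "persistence_fraction": 0.3333333333333333,
      "mean_sqrt_emergence": 2.5,
      "viable_fraction": 0.75
    },
    "B_L3": {
      "persistence_fraction": 0.6666666666666666,
      "mean_sqrt_emergence": 4.0,
      "viable_fraction": 0.75
    }
  }
}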