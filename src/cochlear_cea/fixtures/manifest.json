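{
  "seed": 0,
  "reconstructed_values": {
    "life_table": {
      "file": "synthetic_sg_lifetable.csv",
      "note": "synthetic Gompertz-Makeham table; NOT national statistics data",
      "makeham_a": 0.0002,
      "gompertz_c": 1.1,
      "max_age": 100,
      "target_life_expectancy_at_birth": 83.0,
      "achieved_life_expectancy_at_birth": 83.0
    },
    "reliability_curve": {
      "file": "reliability_fixture.csv",
      "note": "synthetic points placed on the published linear extrapolation; NOT manufacturer follow-up data",
      "intercept": 0.998749,
      "slope_per_year": 0.002911
    },
    "costs.external_processor_replacement": {
      "value_usd": 5895.74,
      "note": "no published price; calibrated so the cohort-mode simultaneous-vs-bimodal incremental cost equals 53451 USD"
    }
  },
  "published_values": "all other parameter-file cells mirror the published tables verbatim"
}
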