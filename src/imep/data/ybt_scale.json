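{
  "test_type": "YBT",
  "cte": 80.0,
  "fc_intercept": 1.61,
  "fc_male": 0.11,
  "fc_age": 0.05,
  "fc_footsize": -0.04,
  "adjusted_min": -175.0,
  "adjusted_max": 526.0,
  "smoothing": 0.5,
  "log_base": "natural"
}
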