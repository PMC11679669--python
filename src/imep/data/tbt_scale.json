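{
  "test_type": "TBT",
  "cte": 300.0,
  "fc_intercept": 1009.87,
  "fc_male": 10.96,
  "fc_age": -54.58,
  "fc_footsize": -11.90,
  "adjusted_min": -54.0,
  "adjusted_max": 206.0,
  "smoothing": 0.5,
  "log_base": "natural"
}
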