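{
  "test_type": "SLB",
  "cte": 350.0,
  "fc_intercept": 1053.32,
  "fc_male": 6.03,
  "fc_age": -53.41,
  "fc_footsize": -12.46,
  "adjusted_min": -72.0,
  "adjusted_max": 230.0,
  "smoothing": 0.5,
  "log_base": "natural"
}
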