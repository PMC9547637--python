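{
  "fields": [
    {"name": "first_name", "comparator": "dice", "error_rate": 0.01, "frequency": 0.0001},
    {"name": "surname", "comparator": "dice", "error_rate": 0.01, "frequency": 0.0001},
    {"name": "birth_name", "comparator": "dice", "error_rate": 0.01, "frequency": 0.0001},
    {"name": "day_of_birth", "comparator": "binary", "error_rate": 0.005, "frequency": 0.0323},
    {"name": "month_of_birth", "comparator": "binary", "error_rate": 0.005, "frequency": 0.0833},
    {"name": "year_of_birth", "comparator": "binary", "error_rate": 0.005, "frequency": 0.0111},
    {"name": "zip", "comparator": "binary", "error_rate": 0.02, "frequency": 0.0005},
    {"name": "city", "comparator": "dice", "error_rate": 0.02, "frequency": 0.005}
  ],
  "exchange_groups": [["first_name", "surname", "birth_name"]],
  "threshold_tentative": 0.7,
  "threshold_match": 0.9,
  "fixedpoint_bits": 16,
  "ring_bits": 64,
  "weight_scale": 256
}
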