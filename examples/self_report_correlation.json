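{
  "trt": {"mean": 1.6, "sd": 0.11, "icc": 0.8, "n": 12, "k": 2},
  "new": {"sd_ratio": 1.0},
  "tau": 1.0,
  "design": {
    "kind": "correlation",
    "rel_other": 0.7,
    "max_r2_biological": 0.30,
    "alpha": 0.05,
    "power": 0.8,
    "sides": "two"
  }
}
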