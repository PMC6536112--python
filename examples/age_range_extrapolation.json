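{
  "trt": {"mean": 1.6, "sd": 0.11, "icc": 0.32, "n": 12, "k": 2},
  "new": {"sd_ratio": 3.2},
  "tau": 1.0
}
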