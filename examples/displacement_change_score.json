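{
  "trt": {"mean": -12.0, "sd": 10.0, "sem": 10.323759005323593, "n": 12, "k": 2},
  "new": {
    "groups": {"n1": 20, "mean1": -12.0, "sd1": 10.0,
               "n2": 20, "mean2": -30.0, "sd2": 10.0}
  },
  "tau": 1.0,
  "design": {
    "kind": "two_sample_t",
    "d_true": 1.8,
    "n1": 20,
    "n2": 20,
    "alpha": 0.05,
    "power": 0.8,
    "sides": "one"
  }
}
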