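# High-reliability, high-variance outcome: reliability is no obstacle, but a
# given percentage difference corresponds to a small standardized effect.
trt:
  mean: 3.5
  sd: 1.4
  icc: 0.9
  n: 12
  k: 2
new:
  sd_ratio: 1.0
tau: 1.0
design:
  kind: two_sample_t
  d_true: 0.8
  n1: 20
  n2: 20
  alpha: 0.05
  power: 0.8
  sides: two
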