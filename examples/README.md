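# Worked examples

Each JSON/YAML file is a study description consumed by `relex feasibility`.
They cover the typical planning scenarios for the toolkit:

1. **`age_range_extrapolation.json`** — a tracer validated in a homogeneous
   healthy sample (ICC 0.32) applied to a planned correlation across a wide
   age range whose SD is 3.2-fold larger. The extrapolated ICC is 0.934:
   low published reliability does not preclude a reliable applied study.

   ```
   relex feasibility examples/age_range_extrapolation.json --round 4
   ```

2. **`self_report_correlation.json`** — planned correlation between an
   outcome with reliability 0.8 and a self-report scale with reliability
   0.7, powered for the maximum realistic explained variance of 30%.
   Attenuation is 0.748; the best-case sample size of 24 grows to 44 once
   measurement error is taken into account.

   ```
   relex feasibility examples/self_report_correlation.json --round 4
   ```

3. **`displacement_change_score.json`** — a change-score (pre/post
   displacement) outcome. Because a change score is the difference of two
   measurements, its SEM is `sqrt(2) * 7.3` here (supplied explicitly as
   `trt.sem`, which takes precedence over `sd`/`icc`). Within one group the
   change-score ICC is negative (-0.066); with a patient group showing 2.5x
   the mean change, the combined 20+20 sample raises it to 0.41, and a true
   d of 1.8 is attenuated to 0.95.

   ```
   relex feasibility examples/displacement_change_score.json --round 4
   ```

   Single-measurement SDDs for the same error level (sigma_e = 7.3/sqrt(2)):

   ```
   relex sdd --sem 5.1619 --n 2        # -> 14.31 (individual), 10.12 (n=2)
   ```

4. **`high_variance_tracer.yaml`** — a high-reliability, high-variance
   outcome, where attenuation is mild and the question is purely one of
   effect size versus sample size.

5. **Required group separation for a ratio outcome** (no study file — it is
   an inversion, not a feasibility run): with test-retest ICC 0.5 and two
   groups of 20 with equal within-group SDs, the Cohen's d needed for the
   pooled sample to reach reliability 0.7 / 0.8 / 0.9:

   ```
   relex required-d --icc 0.5 --sd-trt 1 --n1 20 --n2 20 --target 0.7
   relex required-d --icc 0.5 --sd-trt 1 --n1 20 --n2 20 --target 0.8
   relex required-d --icc 0.5 --sd-trt 1 --n1 20 --n2 20 --target 0.9
   ```

   giving d = 1.64, 2.44 and 3.96 — all unrealistically large
   (`relex overlap --d 1.64` shows U3 > 0.94), so such a design could only
   detect effects no one should expect.
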