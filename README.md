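# relex — reliability extrapolation and study feasibility

`relex` answers a question every individual-differences study should ask
*before* data collection: **is the outcome measure reliable enough, in the
sample you actually plan to recruit, for the study to answer its
question?**

Test–retest reliability is usually reported for young, healthy validation
samples with limited between-subject spread, so the published ICC need not
describe a clinical or wide-range applied sample at all. For costly or
invasive measurements (PET imaging is the motivating case: one scan can
cost over $10,000 and exposes the participant to radioactivity), repeating
the validation study in every new population is not realistic. `relex`
instead extrapolates reliability from published summary statistics alone,
and carries the result through measurement-error metrics, effect-size
attenuation and power analysis into a single feasibility verdict.

## The model

Classical test theory decomposes observed variance into true and error
parts; reliability is

  ρ = σ²_t / (σ²_t + σ²_e).

From a balanced test–retest study, ρ is estimated by the two-way,
absolute-agreement, single-measurement intraclass correlation:

  ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)),

and the absolute measurement uncertainty by the standard error of
measurement, SEM = s·√(1 − ICC), where s is the SD of all measurements.
The toolkit is built on the observation that, if the SEM transfers between
samples (optionally inflated by a factor τ ≥ 1), the reliability expected
in a new sample follows from its SD alone:

  ICC_new = 1 − (τ·SEM)² / s²_new.

Around this core sit:

- **SEM / WSCV / SDD** — absolute and relative uncertainty, and the
  smallest detectable difference √2·z_(1−α/2)·σ̂_e for individuals and
  group means;
- **attenuation** — an observed correlation shrinks to
  r_obs = r_true·√(ρ_A·ρ_B); Cohen's d attenuates through the
  point-biserial conversion r = d/√(d² + a), a = (n₁+n₂)²/(n₁n₂);
- **two-group composition** — the pooled-sample SD from per-group (n, μ,
  σ), inverted to find the group separation (and required Cohen's d) at
  which a pooled sample reaches a target reliability;
- **power** — Fisher-z sample sizes for correlations, exact noncentral-t
  power for t-tests, and the "maximum realistic biological effect size"
  feasibility workflow;
- **simulation** — synthetic test–retest data with known variance
  components for validation and demonstration.

## Worked example

A receptor-imaging outcome was validated in a homogeneous healthy sample:
ICC 0.32 — apparently useless. But the planned applied study spans a wide
age range whose SD is 3.2× larger:

```
$ relex extrapolate --icc 0.32 --sd-ratio 3.2 --round 4
{
  "icc_new": 0.9336,
  "sem_used": 0.8246,
  "sd_ratio": 3.2,
  ...
}
```

The extrapolated reliability is 0.93 — excellent. Conversely, a planned
correlation between a measure with reliability 0.8 and a self-report scale
with reliability 0.7, powered for a maximum realistic explained variance
of 30% (80% power, α = 0.05, two-sided):

```
$ relex power corr --r2 0.30 --rel-a 0.8 --rel-b 0.7 --round 4
{
  "r_max": 0.5477,
  "r_observable": 0.4099,
  "attenuation": 0.7483,
  "n_unattenuated": { "n_fractional": 23.7436, "n_required": 24, ... },
  "n_attenuated":   { "n_fractional": 44.3906, "n_required": 44, ... },
  "classification": "good"
}
```

The best-case correlation of 0.55 would need 24 participants; after
attenuation by measurement error (0.55 → 0.41), 44 are needed. If only 30
can be scanned, the study is miscalibrated for its own most optimistic
premise — a conclusion reached before spending anything.

Finally, how large a group difference would a poorly reliable ratio
outcome (ICC 0.5) need before a 20 + 20 comparison becomes trustworthy at
reliability 0.8?

```
$ relex required-d --icc 0.5 --sd-trt 1 --n1 20 --n2 20 --target 0.8 --round 4
{
  "d": 2.4393,
  "mu2": 2.4393,
  "sd_total_required": 1.5811,
  "target_icc": 0.8
}
```

A Cohen's d of 2.4 (`relex overlap --d 2.4` → U3 = 0.99) — unrealistically
large, so the outcome should not be used for between-group comparisons.

Whole study descriptions can be run end-to-end from a JSON/YAML file with
`relex feasibility <file>`; see `examples/` for the schema and four worked
scenarios. Raw test–retest CSVs (columns `subject,occasion,value`) are
analysed with `relex icc --data trt.csv`, and synthetic datasets with known
variance components come from `relex simulate`.

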