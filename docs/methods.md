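# Methods

## Model and estimation

All computations assume the classical test-theory decomposition
`observed = true + error`, with reliability ρ = σ²_t/(σ²_t + σ²_e).
From balanced test–retest data (n subjects × k occasions, occasion labels
1..k per subject) the package estimates reliability as ICC(A,1) — two-way
mixed effects, absolute agreement, single measurement — from the two-way
ANOVA mean squares, and the error SD as the root within-subject mean
square, σ̂_e = √MS_W. Estimates can be negative although true reliability
cannot; estimation functions return the raw value with a flag, while
conversions that require ρ ∈ [0, 1] (e.g. SEM from ICC) truncate negatives
to zero with a warning. Unbalanced data are rejected with an error naming
the offending subjects rather than silently dropped; `--complete-cases`
(or `TestRetestData.complete_cases()`) performs the drop explicitly.
Constant data (zero total variance) are an error: reliability is undefined
there.

The ICC(1,1) one-way form, average-measure ICCs, and ICC confidence
intervals are deliberately out of scope; in practice ICC(1,1) ≈ ICC(A,1)
for test–retest designs, and the single-measurement absolute-agreement
form is the appropriate one.

## Extrapolation

The core operation rewrites ICC = 1 − SEM²/s² and transfers the SEM:
`ICC_new = 1 − (τ·SEM)²/s²_new`. Three assumptions are attached to every
result as an audit trail (they are stated, never checked numerically):
the error SD transfers up to the factor τ; the error is roughly
homoscedastic across the outcome's range; the data are approximately
normal. The method cannot extrapolate reliability for non-Gaussian
outcomes.

τ is multiplicative on the SEM (variance scales by τ²). τ = 1.2 encodes
"20% more measurement error in the new sample"; τ < 1 claims the new
study measures better than the validation study and therefore requires an
explicit `allow_deflation` override. Negative extrapolated ICCs are
returned unclamped with a machine-readable flag — they are informative
(error variance exceeds total variance expected in the new sample) — but
power routines refuse them. Covariate adjustment is supported only in the
sense the method defines: the caller passes the residual SD after
covariates as `sd_new`; no regression is performed here.

When a summary carries both `sd`+`icc` and an explicit `sem`, the explicit
`sem` wins (published tables sometimes report SEM directly) and a
consistency note is attached if the two disagree.

### Change scores and the error convention

A change score Δ = y_post − y_pre carries the error of two measurements,
so its error variance is 2σ²_e and `ICC_Δ = 1 − 2(τσ_e)²/sd²_Δ`. Two
conventions coexist in practice for deriving σ_e from a reported SD of
test–retest differences, sd_diff:

- for the *smallest detectable difference*, sd_diff already is the SD of
  a difference, so σ_e = sd_diff/√2 (`sigma_e_from_sd_of_differences`)
  and SDD = z·sd_diff;
- for a *change-score reliability* in which sd_diff is treated as the
  per-measurement error SD, the doubled variance 2·sd_diff² enters
  directly.

Because both readings appear in applied work, σ_e is always an explicit
argument; the package never hard-codes one reading as correct. The shipped
change-score example uses the first for SDDs and the second for ICC_Δ,
matching how such analyses are typically reported.

## Two-group composition

The pooled SD of two groups uses sample (n−1) denominators throughout.
Solving it for μ₂ at a target total SD is a quadratic with vertex at μ₁;
the `branch` argument selects the root (default `upper`, μ₂ ≥ μ₁, the
patient-group-higher convention), which makes the inversion deterministic.
A cancellation guard treats a discriminant within ~1e−12 of zero (relative
to its constituent terms) as exactly zero, so a target sitting exactly at
the coincident-means minimum round-trips instead of erroring. Targets
below the minimum achievable total SD raise.

`required_d_for_reliability` chains the SD inversion with the quadratic
solve and reports d with the (n−1)-weighted two-group pooled SD as the
denominator; with equal group SDs this reduces to the common σ, and the
test–retest mean used for μ₁ cancels out of d.

## Effect sizes and attenuation

Correlations attenuate by √(ρ_A·ρ_B) (inclusive bounds, so r_true = 1 is
a legal "best case"). For Cohen's d between two groups, group membership
is taken as measured without error, so only the outcome's reliability
attenuates the effect; the computation converts d to the point-biserial r
with size factor a = (n₁+n₂)²/(n₁n₂) (equal groups: a = 4), attenuates on
the correlation scale, and converts back. This conversion chain — not a
naive d·√ρ — is the package's definition of d attenuation.

Overlap descriptors assume two unit-variance normal populations:
U3 = Φ(|d|), OVL = 2Φ(−|d|/2), CLES = Φ(|d|/√2). No small-sample
(Hedges) correction and no nonparametric CLES are provided.

## Power

- **Correlations**: Fisher-z approximation,
  n = ((z_{1−α/2} + z_{power})/atanh r)² + 3, with **n rounded to the
  nearest integer**. Nearest-integer (rather than ceiling) is the
  convention that keeps the fractional and integer answers consistent
  across the attenuated and unattenuated branches of the feasibility
  workflow; the convention string is embedded in every `PowerResult`.
- **t-tests**: exact noncentral-t power, noncentrality d√n (one-sample and
  paired, d on the change-score scale) or d√(n/2) (two-sample, n per
  group); the required n is the smallest integer meeting the target
  power (no normal approximation). Two-sided is the default everywhere;
  one-sided tests need an explicit flag.
- **SDD vs power**: the SDD uses the normal quantile z, per its
  definition as a measurement-uncertainty bound, and is not a power
  analysis; no small-sample t variant is offered.
- `sample_size_inflation` reports the ratio of *fractional* sample sizes
  (continuous n solved from the noncentral-t power function, keeping
  df ≥ 0.5 where the numerics are sound) at the attenuated versus true
  effect size, as a percentage. Fractional-n conventions differ across
  software, and the paired case additionally depends on the assumed
  pre–post correlation, so this quantity should be read as an order of
  magnitude, not a universal constant.
- Feasibility routines refuse non-positive reliabilities with a pointer
  to the extrapolation flags.

## Units

All percent-scale quantities (WSCV, SDDs on percent-change outcomes) are
plain reals in the caller's units; the library never multiplies by 100.
Only the CLI's `--round` option formats for display. This avoids
double-scaling bugs when chaining operations.

## Synthetic data

`simulate_trt` draws subject true scores Normal(mean, var_true) and adds
independent Normal(0, var_error) noise per occasion — exactly the model
behind ρ — using `numpy.random.default_rng` (PCG64) with the seed recorded
in the output metadata; the same seed yields byte-identical CSVs.
`simulate_two_group` interprets each group's `sd` as the *observed*
single-occasion SD, so true-score variance is sd² − var_error and the
empirical combined SD matches the two-group algebra in expectation.

The generator is deliberately Gaussian, homoscedastic and drift-free
(no true change between occasions), matching the extrapolation method's
own assumptions. Passing tests therefore validate the estimators and the
algebra under the model's assumptions; they say nothing about robustness
to skewed outcomes, heteroscedastic error, or genuine within-subject
change — on such data the extrapolation itself is out of its domain.

Default validation scales: oracle agreement uses ~50–60 random datasets
of up to 15×4; parameter recovery uses 2000 replicates of n = 50, k = 2
(median ICC within ±0.02 of the generating ρ = 0.8); Monte-Carlo power
uses 200,000 simulated two-sample tests (agreement within ±0.005). These
sizes make the checks sharp while keeping the full suite fast.

## Known limitations

- Extrapolation is a rough approximation for planning, not an estimator
  with quantified uncertainty; no confidence intervals are produced.
- Only two-group compositions are supported (no ≥3 groups, no
  Welch-style unequal-variance effect sizes).
- Reliability near or below zero ends the analysis with flags rather
  than attempting inference through it — by design.
- The threshold schemes are conventions, not tests; the classification
  output reports all four bands so the choice is visible.
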