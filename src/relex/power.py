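"""Power and sample size for correlations and t-tests, reliability-aware.

Correlation sample sizes use the Fisher-z approximation

    n = ((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3,

with the fractional n rounded to the *nearest* integer (the convention
carried in every result).  t-test power is exact noncentral t, with
noncentrality d*sqrt(n) (one-sample, paired on the change-score scale) or
d*sqrt(n/2) (two-sample, n per group).

The feasibility routines implement the maximum-realistic-effect workflow:
posit the largest biologically plausible strength of association, attenuate
it by the (possibly extrapolated) reliabilities of the measures, and ask
whether the attainable sample supports even that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import optimize
from scipy.stats import nct, norm, t as t_dist

from .effect_size import attenuate_d, attenuate_r
from .variance_components import TestRetestSummary, classify_reliability

T_FAMILIES = ("one_sample_t", "paired_t", "two_sample_t")
CORR_ROUNDING = "fisher-z approximation; n_fractional rounded to nearest integer"
T_ROUNDING = "exact noncentral-t power; smallest integer n meeting the target"


@dataclass(frozen=True)
class PowerResult:
    """Sample-size answer plus the convention that produced the integer n.

    For two-sample tests n counts subjects *per group*.
    """

    n_fractional: float
    n_required: int
    achieved_power: float
    convention: str

    def to_dict(self) -> dict:
        return {
            "n_fractional": self.n_fractional,
            "n_required": self.n_required,
            "achieved_power": self.achieved_power,
            "convention": self.convention,
        }


def _check_alpha_power(alpha: float, power: float, sides: str) -> None:
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")


def n_for_correlation(r: float, alpha: float = 0.05, power: float = 0.8,
                      sides: str = "two") -> PowerResult:
    """Sample size to detect a correlation ``r`` via the Fisher-z formula."""
    if not 0 < r < 1:
        raise ValueError("r must lie in (0, 1)")
    _check_alpha_power(alpha, power, sides)
    z_alpha = norm.ppf(1.0 - alpha / (2 if sides == "two" else 1))
    z_power = norm.ppf(power)
    zr = math.atanh(r)
    n_frac = ((z_alpha + z_power) / zr) ** 2 + 3.0
    n_req = max(int(math.floor(n_frac + 0.5)), 4)
    achieved = float(norm.cdf(zr * math.sqrt(n_req - 3) - z_alpha))
    return PowerResult(n_fractional=float(n_frac), n_required=n_req,
                       achieved_power=achieved, convention=CORR_ROUNDING)


def power_t_test(d: float, n: float, family: str = "two_sample_t",
                 alpha: float = 0.05, sides: str = "two") -> float:
    """Exact noncentral-t power of a t-test at effect size d and size n.

    ``n`` may be fractional (continuous df), which supports root-finding.
    """
    if family not in T_FAMILIES:
        raise ValueError(f"family must be one of {T_FAMILIES}")
    _check_alpha_power(alpha, 0.5, sides)
    if n <= 1:
        raise ValueError("n must exceed 1")
    if family == "two_sample_t":
        df = 2.0 * n - 2.0
        ncp = d * math.sqrt(n / 2.0)
    else:
        df = n - 1.0
        ncp = d * math.sqrt(n)
    if sides == "one":
        t_crit = t_dist.ppf(1.0 - alpha, df)
        return float(nct.sf(t_crit, df, ncp))
    t_crit = t_dist.ppf(1.0 - alpha / 2.0, df)
    return float(nct.sf(t_crit, df, ncp) + nct.cdf(-t_crit, df, ncp))


def _n_fractional_t(d: float, family: str, alpha: float, power: float,
                    sides: str, upper: float) -> float:
    """Continuous n solving power(n) = power (df interpolated).

    The lower bracket keeps df >= 0.5; the noncentral-t numerics degrade
    as df -> 0.  Effect sizes large enough to need fewer than 1.5 subjects
    report that floor.
    """
    lo = 1.5
    f = lambda n: power_t_test(d, n, family, alpha, sides) - power
    if f(lo) >= 0:
        return lo
    hi = max(upper, 2.0)
    while f(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def n_for_t_test(d: float, family: str = "two_sample_t", alpha: float = 0.05,
                 power: float = 0.8, sides: str = "two") -> PowerResult:
    """Smallest integer n (per group for two-sample) achieving the power."""
    if d <= 0:
        raise ValueError("d must be > 0")
    _check_alpha_power(alpha, power, sides)
    n = 2
    while power_t_test(d, n, family, alpha, sides) < power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("required n exceeds 1e7; check inputs")
    n_frac = _n_fractional_t(d, family, alpha, power, sides, upper=n + 1.0)
    achieved = power_t_test(d, n, family, alpha, sides)
    return PowerResult(n_fractional=n_frac, n_required=n,
                       achieved_power=achieved, convention=T_ROUNDING)


@dataclass
class CorrelationFeasibility:
    """Outcome of the maximum-realistic-association feasibility check."""

    r_max: float
    r_observable: float
    attenuation: float
    n_unattenuated: PowerResult
    n_attenuated: PowerResult
    classification: str
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r_max": self.r_max,
            "r_observable": self.r_observable,
            "attenuation": self.attenuation,
            "n_unattenuated": self.n_unattenuated.to_dict(),
            "n_attenuated": self.n_attenuated.to_dict(),
            "classification": self.classification,
            "flags": list(self.flags),
        }


def _as_reliability(rel) -> float:
    value = rel.icc if isinstance(rel, TestRetestSummary) else float(rel)
    if not 0 < value <= 1:
        raise ValueError(
            "outcome reliability must lie in (0, 1]; a non-positive "
            "extrapolated ICC cannot support a correlation study "
            "(see extrapolation flags)")
    return value


def feasibility_correlation(rel_outcome, rel_other: float,
                            max_r2_biological: float, alpha: float = 0.05,
                            power: float = 0.8,
                            sides: str = "two") -> CorrelationFeasibility:
    """Would the planned correlation study work even in the best case?

    ``max_r2_biological`` is the largest variance fraction the predictor
    could realistically explain; its square root is the best-case true
    correlation, which is then attenuated by both measures' reliabilities.
    Both the best-case and attenuated sample sizes are returned; if the
    attainable sample is below the attenuated one, the study cannot answer
    its question even under its own most optimistic premise.
    """
    rel_out = _as_reliability(rel_outcome)
    if not 0 <= rel_other <= 1:
        raise ValueError("rel_other must lie in [0, 1]")
    if not 0 < max_r2_biological <= 1:
        raise ValueError("max_r2_biological must lie in (0, 1]")
    r_max = math.sqrt(max_r2_biological)
    if r_max >= 1.0:
        r_max = 1.0 - 1e-12
    r_obs = attenuate_r(r_max, rel_out, rel_other)
    return CorrelationFeasibility(
        r_max=r_max,
        r_observable=r_obs,
        attenuation=math.sqrt(rel_out * rel_other),
        n_unattenuated=n_for_correlation(r_max, alpha, power, sides),
        n_attenuated=n_for_correlation(r_obs, alpha, power, sides),
        classification=classify_reliability(rel_out, "koo_li"),
    )


@dataclass(frozen=True)
class InflationResult:
    """Relative sample-size cost of unreliability, as a percentage."""

    percent: float
    d_true: float
    d_observed: float
    convention: str

    def to_dict(self) -> dict:
        return {
            "percent": self.percent,
            "d_true": self.d_true,
            "d_observed": self.d_observed,
            "convention": self.convention,
        }


def sample_size_inflation(d_true: float, reliability: float,
                          family: str = "two_sample_t", alpha: float = 0.05,
                          power: float = 0.8,
                          sides: str = "two") -> InflationResult:
    """Ratio (%) of the fractional n at the attenuated vs the true d.

    Uses continuous (fractional) sample sizes from the noncentral-t power
    function, so the ratio is not quantized by integer rounding; equal
    group sizes are assumed for the d attenuation.
    """
    if d_true <= 0:
        raise ValueError("d_true must be > 0")
    if not 0 < reliability <= 1:
        raise ValueError("reliability must lie in (0, 1]")
    d_obs = attenuate_d(d_true, reliability, 1, 1)
    n_true = n_for_t_test(d_true, family, alpha, power, sides).n_fractional
    n_obs = n_for_t_test(d_obs, family, alpha, power, sides).n_fractional
    return InflationResult(
        percent=100.0 * n_obs / n_true,
        d_true=d_true,
        d_observed=d_obs,
        convention="ratio of fractional n from exact noncentral-t power, "
                   "attenuated vs true effect size, as a percentage",
    )
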