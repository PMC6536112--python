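"""Two-group sample algebra: pooled total SD, its inversion, required d.

When a planned study compares two groups, the total variance that enters a
reliability calculation is that of the *combined* sample, which grows with
the separation between the group means.  With per-group sizes, means and
SDs the combined sample SD is (sample, n-1 denominators):

    sd_total^2 = [ (n1-1) s1^2 + n1 m1^2 + (n2-1) s2^2 + n2 m2^2
                   - (n1+n2) m_total^2 ] / (n1 + n2 - 1).

Fixing everything but m2, this is a quadratic in m2, so one can solve for
the group separation — and hence the Cohen's d — that pushes the combined
sample's extrapolated reliability up to a chosen target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .extrapolation import required_sd_for_target
from .variance_components import TestRetestSummary


@dataclass(frozen=True)
class GroupSpec:
    """One group's size, mean and within-group SD (outcome units)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd <= 0:
            raise ValueError("group sd must be > 0")


@dataclass(frozen=True)
class CombinedSample:
    n_total: int
    mean_total: float
    sd_total: float


def combined_sample_mean(g1: GroupSpec, g2: GroupSpec) -> float:
    """Size-weighted mean of the pooled sample."""
    n_total = g1.n + g2.n
    return (g1.n * g1.mean + g2.n * g2.mean) / n_total


def combined_sample_sd(g1: GroupSpec, g2: GroupSpec) -> float:
    """Sample SD of the two groups pooled into one sample."""
    n_total = g1.n + g2.n
    if n_total < 3:
        raise ValueError("combined sample needs n1 + n2 >= 3")
    mu_total = combined_sample_mean(g1, g2)
    num = ((g1.n - 1) * g1.sd ** 2 + g1.n * g1.mean ** 2
           + (g2.n - 1) * g2.sd ** 2 + g2.n * g2.mean ** 2
           - n_total * mu_total ** 2)
    return math.sqrt(max(num, 0.0) / (n_total - 1))


def combine(g1: GroupSpec, g2: GroupSpec) -> CombinedSample:
    return CombinedSample(
        n_total=g1.n + g2.n,
        mean_total=combined_sample_mean(g1, g2),
        sd_total=combined_sample_sd(g1, g2),
    )


def solve_mu2(g1: GroupSpec, n2: int, sd2: float, sd_total_target: float,
              branch: str = "upper") -> float:
    """Mean of group 2 that makes the combined sample SD hit the target.

    The defining relation is quadratic in mu2 with vertex at mu1, so roots
    come in a symmetric pair: ``upper`` returns mu2 >= mu1, ``lower`` the
    mirror root.  Raises if the target is below the smallest combined SD
    attainable (coincident means).
    """
    if branch not in ("upper", "lower"):
        raise ValueError("branch must be 'upper' or 'lower'")
    if n2 < 2:
        raise ValueError("n2 must be >= 2")
    if sd2 <= 0:
        raise ValueError("sd2 must be > 0")
    if sd_total_target <= 0:
        raise ValueError("sd_total_target must be > 0")
    n1, mu1, sd1 = g1.n, g1.mean, g1.sd
    n_total = n1 + n2
    # (n_total-1) sd_t^2 = (n1-1)s1^2 + n1 mu1^2 + (n2-1)s2^2 + n2 mu2^2
    #                      - (n1 mu1 + n2 mu2)^2 / n_total
    # collect in mu2:  a mu2^2 + b mu2 + c = 0
    a = n2 - n2 ** 2 / n_total            # = n1 n2 / n_total > 0
    b = -2.0 * n1 * n2 * mu1 / n_total
    c_terms = ((n1 - 1) * sd1 ** 2, n1 * mu1 ** 2, (n2 - 1) * sd2 ** 2,
               -n1 ** 2 * mu1 ** 2 / n_total,
               -(n_total - 1) * sd_total_target ** 2)
    c = sum(c_terms)
    disc = b * b - 4.0 * a * c
    # cancellation guard: when the target sits at the coincident-means
    # minimum, rounding in c's large opposing terms can push disc below 0
    scale = b * b + 4.0 * a * sum(abs(t) for t in c_terms) + 1.0
    if -1e-12 * scale <= disc < 0:
        disc = 0.0
    if disc < 0:
        raise ValueError(
            "target total SD unattainable (below minimum achievable)")
    half_width = math.sqrt(disc) / (2.0 * a)
    return mu1 + half_width if branch == "upper" else mu1 - half_width


def pooled_sd(g1: GroupSpec, g2: GroupSpec) -> float:
    """Two-group pooled SD with (n-1) weights (Cohen's d denominator)."""
    return math.sqrt(((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2)
                     / (g1.n + g2.n - 2))


def required_d_for_reliability(trt: TestRetestSummary, n1: int, n2: int,
                               target_icc: float, tau: float = 1.0,
                               sd_ratio_2to1: float = 1.0) -> float:
    """Between-group Cohen's d needed for the combined sample's extrapolated
    reliability to reach ``target_icc``.

    Within-group SDs are sigma1 = trt.sd and sigma2 = sd_ratio_2to1 * sigma1;
    the test-retest mean stands in for mu1 (it cancels from d when the SDs
    are equal).
    """
    sigma1 = trt.sd
    sigma2 = sd_ratio_2to1 * sigma1
    sd_required = required_sd_for_target(trt, target_icc, tau=tau)
    g1 = GroupSpec(n=n1, mean=trt.mean, sd=sigma1)
    mu2 = solve_mu2(g1, n2, sigma2, sd_required, branch="upper")
    g2 = GroupSpec(n=n2, mean=mu2, sd=sigma2)
    return (mu2 - trt.mean) / pooled_sd(g1, g2)
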