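"""Effect sizes, their attenuation by unreliability, and overlap measures.

An observed correlation between two imperfectly measured variables is the
true correlation shrunk by the geometric mean of their reliabilities
(Spearman's attenuation):

    r_obs = r_true * sqrt(rho_A * rho_B).

Standardized mean differences attenuate through the same relation after a
point-biserial conversion to the correlation scale.  Overlap descriptors
(Cohen's U3, the overlap coefficient OVL, the common-language effect size
CLES) translate a Cohen's d into distributional statements under the
equal-variance normal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm


@dataclass(frozen=True)
class OverlapSummary:
    """Distribution-overlap descriptors for a standardized mean difference.

    u3: fraction of the higher group lying above the lower group's mean.
    ovl: shared area of the two unit-variance normal densities.
    cles: chance a random member of the higher group exceeds a random
    member of the lower group.
    """

    u3: float
    ovl: float
    cles: float

    def to_dict(self) -> dict:
        return {"u3": self.u3, "ovl": self.ovl, "cles": self.cles}


def _check_reliability(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(
            f"{name} must lie in [0, 1]; got {value!r}. Negative extrapolated "
            "reliabilities must be handled upstream (see extrapolation flags)")


def attenuate_r(r_true: float, rel_a: float, rel_b: float) -> float:
    """Attenuate a true correlation by the reliabilities of both measures."""
    if not -1.0 <= r_true <= 1.0:
        raise ValueError("r_true must lie in [-1, 1]")
    _check_reliability(rel_a, "rel_a")
    _check_reliability(rel_b, "rel_b")
    return r_true * math.sqrt(rel_a * rel_b)


def cohens_d(mean1: float, mean2: float, sd_pooled: float) -> float:
    """Standardized mean difference (mean2 - mean1) / sd_pooled."""
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be > 0")
    return (mean2 - mean1) / sd_pooled


def _size_factor(n1: int, n2: int) -> float:
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    return (n1 + n2) ** 2 / (n1 * n2)


def d_to_r(d: float, n1: int = 1, n2: int = 1) -> float:
    """Point-biserial conversion r = d / sqrt(d^2 + a), a = (n1+n2)^2/(n1 n2).

    Equal groups give a = 4.
    """
    a = _size_factor(n1, n2)
    return d / math.sqrt(d * d + a)


def r_to_d(r: float, n1: int = 1, n2: int = 1) -> float:
    """Inverse point-biserial conversion d = r sqrt(a) / sqrt(1 - r^2)."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie in (-1, 1)")
    a = _size_factor(n1, n2)
    return r * math.sqrt(a) / math.sqrt(1.0 - r * r)


def attenuate_d(d_true: float, reliability: float,
                n1: int = 1, n2: int = 1) -> float:
    """Attenuate a group-difference d by the outcome's reliability.

    Group membership is taken as known without error (rho = 1), so only the
    outcome's reliability shrinks the effect.  The computation converts to
    the correlation scale, attenuates, and converts back:

        d_obs = r_to_d( d_to_r(d_true) * sqrt(reliability) ).
    """
    _check_reliability(reliability, "reliability")
    r = d_to_r(d_true, n1, n2)
    r_obs = attenuate_r(r, reliability, 1.0)
    return r_to_d(r_obs, n1, n2)


def overlap_summary(d: float) -> OverlapSummary:
    """U3, OVL and CLES for a Cohen's d under equal-variance normality.

        u3   = Phi(|d|)
        ovl  = 2 Phi(-|d|/2)
        cles = Phi(|d| / sqrt(2))
    """
    a = abs(d)
    return OverlapSummary(
        u3=float(norm.cdf(a)),
        ovl=float(2.0 * norm.cdf(-a / 2.0)),
        cles=float(norm.cdf(a / math.sqrt(2.0))),
    )
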