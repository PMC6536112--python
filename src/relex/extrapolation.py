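"""Extrapolating a published ICC to a planned sample with different spread.

Reliability is calibrated to the between-subject spread of the sample it
was estimated in, so an ICC from a test-retest study of homogeneous
healthy volunteers need not describe a clinical sample.  If the absolute
measurement error transfers (possibly inflated by a factor tau), the
reliability expected in a new sample follows from its SD alone:

    ICC_new = 1 - (tau * SEM_trt)^2 / sd_new^2
            = 1 - tau^2 * sd_trt^2 * (1 - ICC_trt) / sd_new^2.

The same logic covers change-score outcomes (error variance doubles
because two measurements contribute) and inverts to the total SD a sample
would need to reach a target reliability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .variance_components import TestRetestSummary

#: Assumptions behind every extrapolation, carried in result metadata as an
#: audit trail.  They are stated, not checked numerically.
ASSUMPTIONS = (
    "absolute measurement error (sigma_e) transfers to the new sample, "
    "up to the stated inflation factor tau",
    "measurement error is roughly constant across the range of the outcome",
    "outcome values are approximately normally distributed",
)

NONPOSITIVE_FLAG = "extrapolated reliability <= 0"


@dataclass
class ExtrapolationSpec:
    """Inputs for one extrapolation: source summary, target SD, tau.

    tau multiplies the SEM (tau=1.2 means 20% more measurement error in
    the new sample); tau < 1 claims the new study measures *better* than
    the validation study and must be explicitly allowed.
    """

    trt: TestRetestSummary
    sd_new: float
    tau: float = 1.0
    allow_deflation: bool = False

    def __post_init__(self) -> None:
        if self.sd_new <= 0:
            raise ValueError("sd_new must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.tau < 1 and not self.allow_deflation:
            raise ValueError(
                "tau < 1 deflates the measurement error; pass "
                "allow_deflation=True to assert the new study is more precise")


@dataclass
class ExtrapolationResult:
    icc_new: float
    sem_used: float
    sd_ratio: float
    flags: list = field(default_factory=list)
    assumptions: tuple = ASSUMPTIONS

    def to_dict(self) -> dict:
        return {
            "icc_new": self.icc_new,
            "sem_used": self.sem_used,
            "sd_ratio": self.sd_ratio,
            "flags": list(self.flags),
            "assumptions": list(self.assumptions),
        }


def extrapolate_icc(spec: ExtrapolationSpec) -> ExtrapolationResult:
    """Extrapolate the source ICC to a sample with SD ``spec.sd_new``.

    Negative results are returned unclamped (they mean the expected error
    variance exceeds the new sample's total variance) and flagged; power
    routines downstream refuse them.
    """
    trt = spec.trt
    flags = list(trt.flags)
    note = trt.consistency_note()
    if note:
        flags.append(note)
    sem = trt.sem_effective
    icc_new = 1.0 - (spec.tau * sem) ** 2 / spec.sd_new ** 2
    if icc_new <= 0:
        flags.append(NONPOSITIVE_FLAG)
    return ExtrapolationResult(
        icc_new=float(icc_new),
        sem_used=float(sem),
        sd_ratio=float(spec.sd_new / trt.sd),
        flags=flags,
    )


def change_score_icc(sigma_e: float, sd_delta: float, tau: float = 1.0) -> float:
    """Reliability of a within-subject change score.

    A change score is the difference of two measurements, so its error
    variance is 2 sigma_e^2 and

        ICC_delta = 1 - 2 (tau sigma_e)^2 / sd_delta^2,

    where ``sd_delta`` is the between-subject SD of the change scores.
    Returned unclamped; values <= 0 mean the change score is dominated by
    noise.
    """
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    if sd_delta <= 0:
        raise ValueError("sd_delta must be > 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 - 2.0 * (tau * sigma_e) ** 2 / sd_delta ** 2


def required_sd_for_target(trt: TestRetestSummary, target_icc: float,
                           tau: float = 1.0) -> float:
    """Total sample SD needed for the extrapolated ICC to hit ``target_icc``.

    Inverts the extrapolation: sd_required = tau * SEM / sqrt(1 - target).
    """
    if not 0 < target_icc < 1:
        raise ValueError("target_icc must lie in (0, 1)")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return tau * trt.sem_effective / math.sqrt(1.0 - target_icc)
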