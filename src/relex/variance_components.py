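"""Reliability as a variance decomposition: ICC estimation, SEM, WSCV and SDD.

Classical test theory treats every observed score as a true score plus
measurement error, so reliability is the fraction of total variance carried
by true between-subject differences,

    rho = sigma_t^2 / (sigma_t^2 + sigma_e^2).

For physiological outcomes this is estimated from a balanced test-retest
study via the two-way, absolute-agreement, single-measurement intraclass
correlation, ICC(A,1).  This module holds the long-format data container,
the ANOVA machinery behind ICC(A,1), the conversions between ICC, the
standard error of measurement (SEM) and the within-subject coefficient of
variation (WSCV), the smallest detectable difference (SDD), and the common
interpretive threshold schemes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class UnbalancedDesignError(ValueError):
    """Raised when the balanced two-way ANOVA formulas do not apply."""


class DegenerateDataError(ValueError):
    """Raised when the data carry zero total variance."""


REQUIRED_COLUMNS = ("subject", "occasion", "value")


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Mean squares of the balanced two-way (subject x occasion) ANOVA.

    ``ms_rows`` is the between-subject mean square (MS_R), ``ms_cols`` the
    between-occasion mean square (MS_C), ``ms_error`` the residual
    interaction mean square (MS_E), and ``ms_within`` the within-subject
    mean square (MS_W), whose square root estimates sigma_e.
    """

    ms_rows: float
    ms_cols: float
    ms_error: float
    ms_within: float
    n_subjects: int
    k_occasions: int

    def __post_init__(self) -> None:
        for name in ("ms_rows", "ms_cols", "ms_error", "ms_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.k_occasions < 2:
            raise ValueError("k_occasions must be >= 2")

    def to_dict(self) -> dict:
        return {
            "ms_rows": self.ms_rows,
            "ms_cols": self.ms_cols,
            "ms_error": self.ms_error,
            "ms_within": self.ms_within,
            "n_subjects": self.n_subjects,
            "k_occasions": self.k_occasions,
        }


@dataclass(frozen=True)
class VarianceComponents:
    """True/error variance decomposition behind a reliability coefficient."""

    var_true: float
    var_error: float

    def __post_init__(self) -> None:
        if self.var_true < 0 or self.var_error < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def var_total(self) -> float:
        return self.var_true + self.var_error

    @property
    def reliability(self) -> float:
        if self.var_total == 0:
            raise DegenerateDataError("degenerate data: zero total variance")
        return self.var_true / self.var_total

    @classmethod
    def from_reliability(cls, reliability: float, var_total: float) -> "VarianceComponents":
        if not 0 <= reliability <= 1:
            raise ValueError("reliability must lie in [0, 1]")
        if var_total < 0:
            raise ValueError("var_total must be non-negative")
        return cls(var_true=reliability * var_total,
                   var_error=(1.0 - reliability) * var_total)


class TestRetestData:
    """Long-format test-retest measurements (subject, occasion, value).

    Wraps a pandas DataFrame; extra columns (e.g. a ``group`` label) are
    preserved.  Occasion labels must be integers >= 1 and unique per
    subject.  The balanced ANOVA formulas additionally require every
    subject to carry the occasions {1..k}; :meth:`check_balanced` enforces
    that and names the offending subjects otherwise.
    """

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        frame = frame.copy()
        frame["occasion"] = frame["occasion"].astype(int)
        values = frame["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite reals")
        if (frame["occasion"] < 1).any():
            raise ValueError("occasion labels must be integers >= 1")
        dup = frame.duplicated(subset=["subject", "occasion"])
        if dup.any():
            bad = frame.loc[dup, "subject"].unique().tolist()
            raise UnbalancedDesignError(
                f"duplicate occasion labels for subjects: {bad}")
        self.frame = frame.reset_index(drop=True)
        self.meta = dict(meta or {})

    # -- constructors -------------------------------------------------
    @classmethod
    def from_records(cls, records, meta: dict | None = None) -> "TestRetestData":
        """Build from an iterable of (subject, occasion, value) triples."""
        frame = pd.DataFrame(records, columns=list(REQUIRED_COLUMNS))
        return cls(frame, meta=meta)

    @classmethod
    def from_csv(cls, path) -> "TestRetestData":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- shape --------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.frame["subject"]))

    def check_balanced(self) -> int:
        """Return k if every subject carries occasions {1..k}; raise otherwise."""
        per_subject = self.frame.groupby("subject", sort=False)["occasion"]
        counts = per_subject.count()
        k = int(counts.mode().max())  # ties resolved toward the fuller design
        if k < 2:
            raise UnbalancedDesignError("each subject needs >= 2 occasions")
        offenders = []
        for subject, occ in per_subject:
            if sorted(occ) != list(range(1, k + 1)):
                offenders.append(subject)
        if offenders:
            raise UnbalancedDesignError(
                f"unbalanced design: subjects {offenders} do not carry "
                f"occasions 1..{k}")
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")
        return k

    def complete_cases(self) -> "TestRetestData":
        """Drop subjects whose occasions differ from the modal set {1..k}."""
        per_subject = self.frame.groupby("subject", sort=False)["occasion"]
        k = int(per_subject.count().mode().iloc[0])
        keep = [s for s, occ in per_subject if sorted(occ) == list(range(1, k + 1))]
        frame = self.frame[self.frame["subject"].isin(keep)]
        return TestRetestData(frame, meta=self.meta)

    def to_matrix(self) -> np.ndarray:
        """Return the n x k value matrix (rows: subjects, cols: occasions)."""
        k = self.check_balanced()
        wide = self.frame.pivot(index="subject", columns="occasion", values="value")
        return wide[list(range(1, k + 1))].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def _anova_mean_squares(data: TestRetestData) -> AnovaMeanSquares:
    y = data.to_matrix()
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        raise DegenerateDataError("degenerate data: zero total variance")
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    ss_within = float(((y - row_means[:, None]) ** 2).sum())
    return AnovaMeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        ms_within=ss_within / (n * (k - 1)),
        n_subjects=n,
        k_occasions=k,
    )


def icc_a1(data: TestRetestData) -> tuple[float, AnovaMeanSquares]:
    """ICC(A,1): two-way mixed effects, absolute agreement, single measurement.

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    The estimate may be negative (true reliability cannot be); callers that
    need rho in [0, 1] truncate downstream.  Requires a balanced design.
    """
    anova = _anova_mean_squares(data)
    n, k = anova.n_subjects, anova.k_occasions
    denom = (anova.ms_rows + (k - 1) * anova.ms_error
             + (k / n) * (anova.ms_cols - anova.ms_error))
    icc = (anova.ms_rows - anova.ms_error) / denom
    return float(icc), anova


def within_subject_error(data: TestRetestData) -> float:
    """Estimate sigma_e as the root of the within-subject mean square,

        sigma_e_hat = sqrt( (1/(n(k-1))) sum_i sum_j (y_ij - ybar_i)^2 ).
    """
    return math.sqrt(_anova_mean_squares(data).ms_within)


def sem_from_icc(sd: float, icc: float) -> float:
    """Standard error of measurement, SEM = s * sqrt(1 - ICC).

    ``sd`` is the sample SD of all measurements (test and retest pooled).
    A negative ICC estimate is truncated to zero (reliability cannot be
    negative) with a warning.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if icc > 1:
        raise ValueError("icc cannot exceed 1")
    if icc < 0:
        warnings.warn("negative ICC estimate truncated to 0 (reliability "
                      "regarded as zero)", stacklevel=2)
        icc = 0.0
    return sd * math.sqrt(1.0 - icc)


def icc_from_sem(sd: float, sem: float) -> float:
    """Invert the SEM relation: ICC = 1 - SEM^2 / s^2 (may be negative)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if sem < 0:
        raise ValueError("sem must be >= 0")
    return 1.0 - (sem / sd) ** 2


def wscv(sem: float, mean: float) -> float:
    """Within-subject coefficient of variation, SEM / |mean| (a fraction)."""
    if mean == 0:
        raise ValueError("mean must be non-zero for WSCV")
    if sem < 0:
        raise ValueError("sem must be >= 0")
    return sem / abs(mean)


def sigma_e_from_sd_of_differences(sd_diff: float) -> float:
    """Recover sigma_e from the SD of test-retest differences.

    The difference of two measurements with independent errors has variance
    2 sigma_e^2, so sigma_e = sd_diff / sqrt(2).
    """
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    return sd_diff / math.sqrt(2.0)


def sdd_individual(sigma_e: float, conf: float = 0.95) -> float:
    """Smallest detectable difference for one subject's change,

        SDD = sqrt(2) * z_{1-alpha/2} * sigma_e,   alpha = 1 - conf.

    A within-subject change smaller than this cannot be distinguished from
    measurement noise at the given confidence.  Uses the normal quantile.
    """
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    if not 0 < conf < 1:
        raise ValueError("conf must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    return math.sqrt(2.0) * z * sigma_e


def sdd_group(sigma_e: float, n: int, conf: float = 0.95) -> float:
    """Smallest detectable difference in the mean of a group of n subjects."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sdd_individual(sigma_e, conf) / math.sqrt(n)


# Interpretive bands: (upper bound exclusive unless noted, label).
_SCHEMES = {
    "koo_li": [
        (0.5, "poor"),
        (0.75, "poor to moderate"),
        (0.9, "good"),
        (math.inf, "excellent (clinical)"),
    ],
    "nunnally": [
        (0.7, "insufficient"),
        (0.8, "lowest acceptable (basic research)"),
        (0.9, "adequate (basic research)"),
        (0.95, "minimum (applied settings)"),
        (math.inf, "adequate (applied settings)"),
    ],
    "fleiss": [
        (0.4, "poor"),
        # Fleiss calls 0.4-0.75 inclusive "good"; handled below.
        (0.75, "good"),
        (math.inf, "excellent"),
    ],
    "cicchetti": [
        (0.4, "poor"),
        (0.6, "fair"),
        (0.75, "good"),
        (math.inf, "excellent"),
    ],
}


def classify_reliability(icc: float, scheme: str = "koo_li") -> str:
    """Map an ICC to the interpretive label of a published threshold scheme.

    Schemes: ``koo_li`` (conservative, for physiological measures with
    negligible true change), ``nunnally`` (internal-consistency standards),
    ``fleiss`` and ``cicchetti`` (traditional test-retest bands).
    """
    if scheme not in _SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; valid schemes: {sorted(_SCHEMES)}")
    if scheme == "fleiss" and icc == 0.75:  # inclusive upper edge of "good"
        return "good"
    for upper, label in _SCHEMES[scheme]:
        if icc < upper:
            return label
    raise AssertionError("unreachable")


@dataclass
class TestRetestSummary:
    """Published summary statistics of a test-retest study.

    ``sd`` is the sample SD of all measurements, in outcome units.  Supply
    ``icc`` and/or ``sem``; a missing one is derived from the other via
    SEM = s sqrt(1 - ICC).  When both are supplied the explicit ``sem``
    wins downstream and any inconsistency is reported (not enforced) via
    :meth:`consistency_note`.
    """

    mean: float
    sd: float
    icc: float | None = None
    n: int = 2
    k: int = 2
    sem: float | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.n < 2 or self.k < 2:
            raise ValueError("n and k must be >= 2")
        if self.icc is None and self.sem is None:
            raise ValueError("supply at least one of icc, sem")
        if self.icc is None:
            self.icc = icc_from_sem(self.sd, self.sem)
        if self.icc > 1:
            raise ValueError("icc cannot exceed 1")
        if self.icc < 0:
            self.flags.append("negative ICC estimate (reliability regarded as zero)")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def sem_effective(self) -> float:
        """The SEM used downstream: explicit if given, else s sqrt(1-ICC)."""
        if self.sem is not None:
            return self.sem
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sem_from_icc(self.sd, self.icc)

    def consistency_note(self, rtol: float = 1e-6) -> str | None:
        """Report (never enforce) disagreement between explicit sem and sd/icc."""
        if self.sem is None or self.icc is None:
            return None
        implied = self.sd * math.sqrt(max(1.0 - self.icc, 0.0))
        if implied == 0 and self.sem == 0:
            return None
        scale = max(abs(implied), abs(self.sem))
        if abs(self.sem - implied) / scale > rtol:
            return (f"explicit sem={self.sem:g} differs from "
                    f"sd*sqrt(1-icc)={implied:g}; explicit sem used")
        return None
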