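"""Synthetic test-retest data with known variance components.

Generates balanced long-format datasets under the additive model
observation = true score + error, with subject true scores drawn
Normal(mean, var_true) and independent Normal(0, var_error) noise per
occasion.  Because the generating reliability var_true/(var_true+var_error)
is known exactly, the output supports parameter-recovery tests and
demonstrations of attenuation and of how between-group separation raises
whole-sample reliability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_composition import GroupSpec
from .variance_components import TestRetestData


@dataclass(frozen=True)
class SimulationSpec:
    """Generating parameters for one balanced test-retest dataset."""

    n_subjects: int
    k_occasions: int = 2
    mean: float = 0.0
    var_true: float = 1.0
    var_error: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.k_occasions < 2:
            raise ValueError("k_occasions must be >= 2")
        if self.var_true < 0 or self.var_error < 0:
            raise ValueError("variances must be non-negative")
        if self.var_true + self.var_error == 0:
            raise ValueError("var_true + var_error must be > 0")

    @property
    def reliability(self) -> float:
        return self.var_true / (self.var_true + self.var_error)


def _long_frame(values: np.ndarray, subjects: np.ndarray) -> pd.DataFrame:
    n, k = values.shape
    return pd.DataFrame({
        "subject": np.repeat(subjects, k),
        "occasion": np.tile(np.arange(1, k + 1), n),
        "value": values.ravel(),
    })


def simulate_trt(spec: SimulationSpec) -> TestRetestData:
    """Draw one balanced test-retest dataset; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    true = spec.mean + math.sqrt(spec.var_true) * rng.standard_normal(spec.n_subjects)
    noise = math.sqrt(spec.var_error) * rng.standard_normal(
        (spec.n_subjects, spec.k_occasions))
    values = true[:, None] + noise
    frame = _long_frame(values, np.arange(1, spec.n_subjects + 1))
    meta = {"seed": spec.seed, "generator": "numpy.random.default_rng (PCG64)",
            "var_true": spec.var_true, "var_error": spec.var_error,
            "mean": spec.mean, "reliability": spec.reliability}
    return TestRetestData(frame, meta=meta)


def simulate_two_group(g1: GroupSpec, g2: GroupSpec, var_error: float,
                       seed: int = 0, k_occasions: int = 2) -> TestRetestData:
    """Two labelled groups sharing one error variance.

    ``GroupSpec.sd`` is the *observed* within-group SD of a single
    occasion, so the true-score variance is sd^2 - var_error (must be
    positive).  The combined single-occasion sample then reproduces the
    two-group pooled-SD algebra in expectation, while within-group
    reliability is 1 - var_error / sd^2.
    """
    if var_error < 0:
        raise ValueError("var_error must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for label, g in (("g1", g1), ("g2", g2)):
        var_true = g.sd ** 2 - var_error
        if var_true <= 0:
            raise ValueError(
                f"group {label}: sd^2 must exceed var_error (observed-score "
                "SD includes the error)")
        true = g.mean + math.sqrt(var_true) * rng.standard_normal(g.n)
        noise = math.sqrt(var_error) * rng.standard_normal((g.n, k_occasions))
        frame = _long_frame(true[:, None] + noise,
                            np.arange(offset + 1, offset + g.n + 1))
        frame["group"] = label
        frames.append(frame)
        offset += g.n
    meta = {"seed": seed, "generator": "numpy.random.default_rng (PCG64)",
            "var_error": var_error, "k_occasions": k_occasions}
    return TestRetestData(pd.concat(frames, ignore_index=True), meta=meta)
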