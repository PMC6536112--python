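"""Independent brute-force oracles used by the tests.

Everything here is written loop-wise / by quadrature, deliberately sharing
no code with the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def loopwise_icc_a1(y) -> float:
    """ICC(A,1) from explicit two-way ANOVA sums of squares, all loops."""
    y = [list(map(float, row)) for row in y]
    n = len(y)
    k = len(y[0])
    total = 0.0
    for i in range(n):
        assert len(y[i]) == k
        for j in range(k):
            total += y[i][j]
    grand = total / (n * k)

    row_means = [sum(y[i]) / k for i in range(n)]
    col_means = [sum(y[i][j] for i in range(n)) / n for j in range(k)]

    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (row_means[i] - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (col_means[j] - grand) ** 2
    ss_error = 0.0
    for i in range(n):
        for j in range(k):
            resid = y[i][j] - row_means[i] - col_means[j] + grand
            ss_error += resid ** 2

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_error / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


def loopwise_sigma_e(y) -> float:
    """Root within-subject mean square, computed with explicit loops."""
    y = [list(map(float, row)) for row in y]
    n = len(y)
    k = len(y[0])
    acc = 0.0
    for i in range(n):
        ybar = sum(y[i]) / k
        for j in range(k):
            acc += (y[i][j] - ybar) ** 2
    return math.sqrt(acc / (n * (k - 1)))


def construct_sample(n: int, mean: float, sd: float) -> np.ndarray:
    """A concrete vector with exactly the requested n, mean and sample SD."""
    base = np.arange(n, dtype=float)
    base[0] += 0.37  # break symmetry so n=2 is fine too
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


def quadrature_ovl(d: float) -> float:
    """Overlap of N(0,1) and N(d,1) by numerical integration."""
    a = abs(d)
    value, _ = quad(lambda x: min(norm.pdf(x), norm.pdf(x - a)),
                    -12.0, a + 12.0, limit=200)
    return value


def monte_carlo_power_two_sample(d: float, n: int, alpha: float, sides: str,
                                 n_reps: int, seed: int) -> float:
    """Empirical power of the two-sample t-test by direct simulation."""
    from scipy.stats import t as t_dist

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n))
    y = d + rng.standard_normal((n_reps, n))
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    sp = np.sqrt((vx + vy) / 2.0)
    t_stat = (y.mean(axis=1) - x.mean(axis=1)) / (sp * math.sqrt(2.0 / n))
    df = 2 * n - 2
    if sides == "one":
        crit = t_dist.ppf(1.0 - alpha, df)
        return float(np.mean(t_stat > crit))
    crit = t_dist.ppf(1.0 - alpha / 2.0, df)
    return float(np.mean(np.abs(t_stat) > crit))
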