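"""Overlap plot: two shaded normal densities a Cohen's d apart."""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .effect_size import overlap_summary


def overlap_plot(d: float, path, ax=None):
    """Draw two unit-variance normal densities separated by ``d``.

    The shared area is shaded and the panel is annotated with U3, OVL and
    CLES.  Returns the matplotlib Axes; writes to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = abs(d)
    x = np.linspace(-4, a + 4, 800)
    f1, f2 = norm.pdf(x, 0, 1), norm.pdf(x, a, 1)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(x, f1, color="#1f77b4", label="group 1")
    ax.plot(x, f2, color="#d62728", label="group 2")
    ax.fill_between(x, np.minimum(f1, f2), color="grey", alpha=0.4)
    s = overlap_summary(d)
    ax.set_title(f"d = {d:g}   U3 = {s.u3:.2f}   OVL = {s.ovl:.2f}   "
                 f"CLES = {s.cles:.2f}")
    ax.set_xlabel("standardized outcome")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
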