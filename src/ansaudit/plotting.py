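"""Convenience plots (matplotlib is an optional dependency)."""

from __future__ import annotations

import numpy as np

from .correlation import CorrelationDistribution
from .slopes import SlopeCurve


def plot_slope_curve(curve: SlopeCurve, ax=None):
    """Ratio effect vs Weber fraction for one ratio pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.w_grid, curve.effects)
    ax.set_xlabel("Weber fraction")
    ax.set_ylabel("ratio effect (overlap difference)")
    ax.set_title(f"ratio pair {curve.pair.label}")
    return ax


def plot_correlation_hist(dist: CorrelationDistribution, bins=50, ax=None):
    """Histogram of simulated Pearson correlations for one grid cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(dist.r_values, bins=np.linspace(-1, 1, bins + 1))
    ax.set_xlabel("Pearson r (Weber fraction vs ratio effect)")
    ax.set_ylabel("replications")
    ax.set_title(f"{dist.pair_label}, {dist.dist_label or 'population'}")
    return ax
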