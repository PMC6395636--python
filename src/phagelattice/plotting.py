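"""Minimal plotting helpers for trajectories and ensembles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import Ensemble
from .engine import Trajectory


def plot_trajectory(trajectory: Trajectory, labels, ax=None):
    """Line plot of counted labels over iterations.

    ``labels`` is an iterable of ``(entity_class, label)`` pairs.
    """
    if ax is None:
        _, ax = plt.subplots()
    for cls, lbl in labels:
        ax.plot(trajectory.iterations, trajectory.series(cls, lbl), label=f"{cls}:{lbl}")
    ax.set_xlabel("iteration")
    ax.set_ylabel("count")
    ax.legend(fontsize="small")
    return ax


def plot_ensemble(ensemble: Ensemble, labels, ax=None, level: float = 0.95):
    """Ensemble mean with shaded confidence band for each counted label."""
    if ax is None:
        _, ax = plt.subplots()
    iters = ensemble.trajectories[0].iterations
    for cls, lbl in labels:
        mean, lo, hi = ensemble.mean_ci(cls, lbl, level=level)
        line, = ax.plot(iters, mean, label=f"{cls}:{lbl}")
        ax.fill_between(iters, lo, hi, alpha=0.25, color=line.get_color())
    ax.set_xlabel("iteration")
    ax.set_ylabel("count")
    ax.legend(fontsize="small")
    return ax
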