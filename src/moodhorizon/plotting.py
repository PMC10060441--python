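"""Curve plots: per-day mean AUC with +/- 1 SE ribbons."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default; no-op if set
import matplotlib.pyplot as plt

from .temporal import ACCEPTABLE_AUC, PerformanceCurve

__all__ = ["plot_curves", "plot_labeled_curves"]


def plot_labeled_curves(
    labeled: Sequence[tuple[str, PerformanceCurve]],
    ax: Optional[plt.Axes] = None,
    threshold: float = ACCEPTABLE_AUC,
):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for label, curve in labeled:
        days, means, ses = curve.days, curve.mean_aucs, curve.se_aucs
        line, = ax.plot(days, means, label=label)
        ax.fill_between(days, means - ses, means + ses,
                        color=line.get_color(), alpha=0.2, linewidth=0)
    ax.axhline(threshold, color="grey", linestyle="--", linewidth=1,
               label=f"acceptable AUC ({threshold:.2f})")
    ax.axhline(0.5, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("day of data collection")
    ax.set_ylabel("mean AUC (±1 SE)")
    ax.set_ylim(0.35, 1.0)
    ax.legend(fontsize=8)
    return ax


def plot_curves(
    curves: Sequence[PerformanceCurve],
    ax: Optional[plt.Axes] = None,
    threshold: float = ACCEPTABLE_AUC,
):
    """One line + ribbon per model configuration."""
    labeled = [
        (f"{c.config.outcome} {c.config.algorithm} ({c.config.predictor_set})", c)
        for c in curves
    ]
    return plot_labeled_curves(labeled, ax=ax, threshold=threshold)
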