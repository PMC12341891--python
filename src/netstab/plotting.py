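"""Plots: stability-curve ribbons, multi-result overlays, AUC bars."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .curvestats import rank_by_auc
from .engine import RobustnessResult

__all__ = ["plot_curves", "plot_auc_bars"]


def _ribbon(ax, cs, label, color=None):
    levels = np.asarray(cs.levels)
    mean = cs.mean_curve()
    lo = cs.values.min(axis=1)
    hi = cs.values.max(axis=1)
    (line,) = ax.plot(levels, mean, marker="o", markersize=3, label=label, color=color)
    ax.fill_between(levels, lo, hi, alpha=0.2, color=line.get_color())


def plot_curves(results: RobustnessResult | Sequence[RobustnessResult], path) -> None:
    """Mean curve with replicate min-max ribbon per (method, condition).

    Accepts one result or several (overlay); nothing is normalized, so the
    lowest curve reads directly as the most robust configuration.
    """
    if isinstance(results, RobustnessResult):
        results = [results]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for ri, result in enumerate(results):
        prefix = f"r{ri}:" if len(results) > 1 else ""
        for cs in result.curves:
            label = f"{prefix}{cs.method}"
            if cs.condition != "observed":
                label += f" ({cs.condition})"
            _ribbon(ax, cs, label)
    ax.set_xlabel("perturbation level (fraction of edges rewired)")
    ax.set_ylabel(f"distance ({results[0].measure})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_auc_bars(result: RobustnessResult, path) -> None:
    """Bar chart of per-method AUC, ascending (best first)."""
    ranking = rank_by_auc(result)
    names = [m for m, _ in ranking]
    values = [v for _, v in ranking]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(names)), values)
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("AUC (lower = more robust)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
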