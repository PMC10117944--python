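"""Figure helpers: spectrum bars, per-group MF boxplots, survival curves.

Matplotlib with the Agg backend; callers pass an output path and get a
saved SVG/PNG.  Boxplots use the 1.5*IQR whisker convention (labelled).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mutation_stats import SPECTRUM_CLASSES, SpectrumSummary
from .survival_model import SurvivalCurve, survival

__all__ = ["spectrum_bars", "mf_boxplot", "survival_plot"]


def spectrum_bars(summaries: dict[str, SpectrumSummary], path: str) -> None:
    """Grouped bar chart of six-class SBS proportions per treatment."""
    fig, ax = plt.subplots(figsize=(8, 4))
    labels = list(summaries)
    width = 0.8 / max(1, len(labels))
    x = np.arange(len(SPECTRUM_CLASSES))
    for i, label in enumerate(labels):
        s = summaries[label]
        total = max(1, s.n_sbs)
        props = [s.counts[c] / total for c in SPECTRUM_CLASSES]
        ax.bar(x + i * width, props, width=width, label=label)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(SPECTRUM_CLASSES, rotation=30, ha="right")
    ax.set_ylabel("proportion of SBSs")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def mf_boxplot(
    per_group_values: dict[str, list[float]],
    path: str,
    letters: dict[str, str] | None = None,
) -> None:
    """Boxplots of per-plant mutation frequency; whiskers at 1.5*IQR."""
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = list(per_group_values)
    data = [per_group_values[g] for g in labels]
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    if letters:
        top = max((max(v) for v in data if len(v)), default=1.0)
        for i, g in enumerate(labels, start=1):
            ax.text(i, top * 1.05, letters.get(g, ""), ha="center")
    ax.set_ylabel("mutation frequency (per bp)")
    ax.set_title("whiskers: 1.5 x IQR")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def survival_plot(
    data: pd.DataFrame, curve: SurvivalCurve, path: str
) -> None:
    """Observed survival fractions with the fitted model overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    frac = data["survivors"] / data["total"]
    ax.scatter(data["dose"], frac, s=12, alpha=0.6, label="observed")
    grid = np.linspace(0, float(data["dose"].max()) * 1.05 or 1.0, 200)
    ax.plot(grid, survival(grid, curve), label=f"fit (Dq={curve.dq:.1f} Gy)")
    ax.set_yscale("log")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("survival fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
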