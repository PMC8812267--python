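"""Minimal figure helpers for the report stage.

These render the statistical outputs as simple channel x band heatmaps and
per-level time-course plots; no topographic interpolation is attempted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_scalp_table(frame: pd.DataFrame, value_col: str, path: str | Path,
                     title: Optional[str] = None) -> Path:
    """Heatmap of a per-(channel, band) statistic (F, p_fdr, or contrast)."""
    plt = _mpl()
    pivot = frame.pivot(index="channel", columns="band", values=value_col)
    fig, ax = plt.subplots(figsize=(4, max(4, 0.18 * len(pivot))))
    im = ax.imshow(pivot.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=5)
    fig.colorbar(im, ax=ax, label=value_col)
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_level_time_courses(courses: Dict[int, np.ndarray], rate: float,
                            path: str | Path, ylabel: str = "μmol/L") -> Path:
    """Per-difficulty-level mean chromophore time-courses."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3))
    for level, trace in sorted(courses.items()):
        t = np.arange(len(trace)) / rate
        ax.plot(t, trace, label=f"level {level}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_accuracy_curve(curve: pd.DataFrame, path: str | Path) -> Path:
    """Mean accuracy vs number of ranked channels, with a dispersion band."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3))
    n = curve["n_channels"]
    m = curve["mean_accuracy"]
    s = curve["std_accuracy"]
    ax.plot(n, m, color="C0")
    ax.fill_between(n, m - s, m + s, alpha=0.3, color="C0")
    ax.set_xlabel("number of channels")
    ax.set_ylabel("accuracy (%)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
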