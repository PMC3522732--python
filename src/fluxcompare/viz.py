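"""Static plot output: relative-flux heat maps and trade-off curves."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def heatmap_figure(percent_matrix: pd.DataFrame, title: str = ""):
    """Heat map of a column-normalized comparative table.

    High relative flux renders light (white = 100 % of the column maximum),
    low renders dark red; absent cells are grey.
    """
    values = percent_matrix.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(percent_matrix.columns),
                 1.0 + 0.35 * len(percent_matrix.index)),
    )
    cmap = plt.get_cmap("Reds_r").copy()
    cmap.set_bad(color="0.7")
    im = ax.imshow(
        np.ma.masked_invalid(values), cmap=cmap, vmin=0, vmax=100, aspect="auto"
    )
    ax.set_xticks(range(len(percent_matrix.columns)))
    ax.set_xticklabels(percent_matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(percent_matrix.index)))
    ax.set_yticklabels(percent_matrix.index)
    fig.colorbar(im, ax=ax, label="% of column maximum")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def pareto_figure(front, title: str = ""):
    """Trade-off plot: objective-2 flux against objective-1 percent of
    maximum, with the feasible region below the curve shaded."""
    frame = front.to_frame().sort_values("obj1_percent")
    fig, ax = plt.subplots(figsize=(5, 4))
    x = frame["obj1_percent"].to_numpy(dtype=float)
    y = frame["obj2_flux"].to_numpy(dtype=float)
    ax.plot(x, y, color="tab:blue", marker="o", markersize=3)
    ax.fill_between(x, 0, y, color="tab:blue", alpha=0.15)
    ax.set_xlabel(f"{front.objective1} (% of maximum)")
    ax.set_ylabel(f"{front.objective2} flux")
    ax.set_xlim(0, 100)
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def save_figure(fig, path: Union[str, Path]) -> None:
    fig.savefig(path, dpi=150)
    plt.close(fig)
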