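"""Figures: cooperation-rate heat maps per punishment-locality panel and
strategy-transition rasters.

Heat maps show the mean cooperation rate over the (g, a) plane, one panel per
value of p, with a on the horizontal and g on the vertical axis.  Rasters
show one trial's strategies as a (generations+1) x N image with generation
increasing upward (bottom row = initial state) and the four-colour strategy
mapping: CP light blue, CN pink, DP red, DN dark blue.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .dynamics import TrialResult

__all__ = ["STRATEGY_COLORS", "render_sweep_heatmaps", "render_history_raster"]

#: CP light blue, CN pink, DP red, DN dark blue (raster colour convention)
STRATEGY_COLORS = ("#87ceeb", "#ffc0cb", "#e03131", "#00008b")


def render_sweep_heatmaps(sweep: pd.DataFrame, path) -> Path:
    """One heat-map panel per value of p; a horizontal, g vertical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    p_values = sorted(sweep["p"].unique())
    fig, axes = plt.subplots(
        1, len(p_values), figsize=(3.1 * len(p_values), 3.2), squeeze=False
    )
    for ax, p in zip(axes[0], p_values):
        panel = (
            sweep[sweep["p"] == p]
            .pivot(index="g", columns="a", values="mean_coop")
            .sort_index()
        )
        im = ax.imshow(
            panel.to_numpy(),
            origin="lower",
            vmin=0.0,
            vmax=1.0,
            cmap="viridis",
            aspect="auto",
        )
        ax.set_xticks(range(len(panel.columns)), [f"{a:g}" for a in panel.columns])
        ax.set_yticks(range(len(panel.index)), [f"{g:g}" for g in panel.index])
        ax.set_xlabel("a")
        ax.set_ylabel("g")
        ax.set_title(f"p = {p:g}")
    fig.colorbar(im, ax=axes[0], shrink=0.85, label="mean cooperation rate")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_history_raster(trial: TrialResult, path) -> Path:
    """Strategy raster of one trial: agent id horizontal, generation upward."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix = trial.strategy_matrix()
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    ax.imshow(
        matrix,
        origin="lower",  # bottom row = generation 0
        cmap=ListedColormap(STRATEGY_COLORS),
        vmin=-0.5,
        vmax=3.5,
        interpolation="nearest",
        aspect="auto",
    )
    ax.set_xlabel("agent id")
    ax.set_ylabel("generation")
    p = trial.params
    ax.set_title(f"(g, p, a) = ({p.g:g}, {p.p:g}, {p.a:g}), seed {trial.seed}")
    ax.legend(
        handles=[
            Patch(color=c, label=s)
            for c, s in zip(STRATEGY_COLORS, ("CP", "CN", "DP", "DN"))
        ],
        loc="upper left",
        bbox_to_anchor=(1.01, 1.0),
        frameon=False,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
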