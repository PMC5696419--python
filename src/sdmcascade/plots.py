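"""Figure helpers: likelihood maps and change bar charts.

Renders the two standard views of a cascade run — a per-horizon likelihood
map (gray historical presence under a red-graded future likelihood scale)
and grouped bar charts of distribution or diversity change with compact
letter annotations.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .cascade import LIKELIHOOD_LABELS, LikelihoodMap

_LIKELIHOOD_COLORS = [
    "#f7f7f7",  # not suitable
    "#fee5d9",
    "#fcae91",
    "#fb6a4a",
    "#de2d26",
    "#a50f15",  # extremely likely
]


def plot_likelihood_map(lmap: LikelihoodMap, path: str | Path, title: str | None = None) -> Path:
    """Render a likelihood map with the historical presence overlay."""
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = ListedColormap(_LIKELIHOOD_COLORS)
    norm = BoundaryNorm(np.arange(-0.5, len(LIKELIHOOD_LABELS)), cmap.N)
    im = ax.imshow(lmap.classes, origin="lower", cmap=cmap, norm=norm)
    if lmap.historical is not None:
        hist = np.ma.masked_where(~lmap.historical, np.ones_like(lmap.classes))
        ax.imshow(hist, origin="lower", cmap=ListedColormap(["#00000055"]), interpolation="none")
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(LIKELIHOOD_LABELS)))
    cbar.ax.set_yticklabels(LIKELIHOOD_LABELS)
    ax.set_title(title or f"{lmap.species} — {lmap.horizon_id}")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_change_bars(
    table: pd.DataFrame,
    path: str | Path,
    letters: dict[str, str] | None = None,
    ylabel: str = "pixels",
) -> Path:
    """Grouped bars of per-state counts, optionally annotated with letters."""
    cols = [c for c in table.columns if c != "most_frequent"]
    fig, ax = plt.subplots(figsize=(1.2 * len(cols) + 3, 4))
    states = list(table.index)
    width = 0.8 / len(states)
    x = np.arange(len(cols))
    for i, st in enumerate(states):
        label = st if letters is None else f"{st} ({letters.get(st, '')})"
        ax.bar(x + i * width, table.loc[st, cols].to_numpy(dtype=float), width, label=label)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([str(c) for c in cols], rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
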