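"""Figure rendering: congruency frequency plots and RDM heatmaps.

Palette RGB values are used here and nowhere else; statistics never
depend on them.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from .data import Dataset
from .errors import ValidationError
from .palette import N_COLORS
from .patterns import compile_pattern
from .rsa import Rdm


def plot_congruency(dataset: Dataset, output_path: str):
    """Stacked congruent-choice frequency plot (one panel per group x odor).

    Within each panel the colors chosen as congruent for that odor are
    stacked bottom-up in decreasing frequency, each box's height
    proportional to its count; box fills use the palette RGB exactly.
    Writes ``output_path`` and returns the figure.
    """
    if dataset.records.empty:
        raise ValidationError("cannot plot an empty dataset")
    groups, odors = dataset.groups, dataset.odors
    rgb = dataset.palette.rgb_float()
    fig, axes = plt.subplots(
        len(odors), len(groups),
        figsize=(1.1 * len(groups) + 1.5, 0.85 * len(odors) + 1.2),
        squeeze=False,
    )
    for oi, odor in enumerate(odors):
        for gi, group in enumerate(groups):
            ax = axes[oi][gi]
            pattern = compile_pattern(dataset, group, odor)
            counts = pattern.congruent
            order = np.argsort(-counts, kind="stable")
            bottom = 0
            for c in order:
                if counts[c] == 0:
                    break
                ax.add_patch(
                    Rectangle((0.1, bottom), 0.8, counts[c],
                              facecolor=rgb[c], edgecolor="none",
                              antialiased=False)
                )
                bottom += counts[c]
            ax.set_xlim(0, 1)
            ax.set_ylim(0, max(bottom, 1))
            ax.set_xticks([])
            ax.set_yticks([])
            if oi == 0:
                ax.set_title(group, fontsize=7)
            if gi == 0:
                ax.set_ylabel(odor, fontsize=7, rotation=0,
                              ha="right", va="center")
    fig.suptitle("Congruent color choices by group and odor", fontsize=9)
    fig.savefig(output_path, dpi=150)
    return fig


def plot_rdm(rdm: Rdm, output_path: str, title: Optional[str] = None):
    """Heatmap of a dissimilarity matrix with the diagonal at the colormap
    minimum; if a null distribution is attached, a density line graph is
    drawn beside the color legend.  Writes ``output_path`` and returns the
    figure.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    vmax = max(float(rdm.matrix.max()), 1e-6)
    im = ax.imshow(rdm.matrix, cmap="turbo", vmin=0.0, vmax=vmax)
    ax.set_xticks(range(len(rdm.labels)))
    ax.set_yticks(range(len(rdm.labels)))
    ax.set_xticklabels(rdm.labels, rotation=90, fontsize=7)
    ax.set_yticklabels(rdm.labels, fontsize=7)
    cbar = fig.colorbar(im, ax=ax, label="dissimilarity (1 - r)")
    if title:
        ax.set_title(title)
    if rdm.null_distribution is not None and rdm.null_distribution.size > 3:
        from scipy.stats import gaussian_kde

        vals = np.asarray(rdm.null_distribution, dtype=float).ravel()
        grid = np.linspace(0.0, vmax, 200)
        try:
            dens = gaussian_kde(vals)(grid)
        except np.linalg.LinAlgError:  # degenerate (constant) null
            dens = np.zeros_like(grid)
        side = fig.add_axes(
            [cbar.ax.get_position().x1 + 0.02,
             cbar.ax.get_position().y0,
             0.08, cbar.ax.get_position().height]
        )
        side.plot(dens, grid, lw=1.0, color="black")
        side.set_ylim(0.0, vmax)
        side.set_xticks([])
        side.set_yticks([])
        side.set_xlabel("null", fontsize=6)
    fig.savefig(output_path, dpi=150)
    return fig
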