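"""Plotting conveniences (not part of the tested analysis surface)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .pangenome import PresenceMatrix


def plot_presence_heatmap(
    matrix: PresenceMatrix,
    genome_order: list[str] | None = None,
    path: str | Path | None = None,
):
    """Presence/absence heatmap (presence red, absence black), genomes
    ordered by *genome_order* (e.g. a dendrogram leaf order)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = list(genome_order) if genome_order else list(matrix.genome_ids)
    rows = [matrix.genome_ids.index(g) for g in order]
    data = matrix.cells[np.array(rows)] if rows else matrix.cells

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(matrix.feature_ids)),
                 max(3, 0.25 * len(order)))
    )
    ax.imshow(data, aspect="auto", cmap=ListedColormap(["black", "#c40000"]),
              vmin=0, vmax=1)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    ax.set_xticks(range(len(matrix.feature_ids)), matrix.feature_ids,
                  rotation=90, fontsize=7)
    ax.set_xlabel("gene feature")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
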