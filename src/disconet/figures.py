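"""Static figure exports: consensus volcano, similarity heat map, overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # file export only; no interactive backend assumed

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .similarity import SimilarityMatrix

_EDGE_COLORS = {
    "pathway∩both": "#000000",
    "pathway∩disease": "#d62728",
    "pathway∩normal": "#1f77b4",
    "pathway-only": "#bbbbbb",
    "coexpression-only": "#999999",
    "membership": "#dddddd",
}
_NODE_COLORS = {"up": "#ff7f0e", "down": "#1f77b4", "none": "#cccccc",
                "mixed": "#9467bd", "unknown": "#cccccc"}


def consensus_volcano(consensus: pd.DataFrame, path,
                      p_cut: float = 0.01, lfc_cut: float = 1.75) -> None:
    """Mean log2FC vs -log10 mean adjusted p, with the extreme-gene cuts."""
    fig, ax = plt.subplots(figsize=(6, 5))
    if not consensus.empty:
        x = consensus["mean_log2fc"]
        y = -np.log10(np.clip(consensus["mean_adj_p"], 1e-300, None))
        ax.scatter(x, y, s=8, c=np.where(consensus["direction"] == "up",
                                         "#ff7f0e", "#1f77b4"), alpha=0.6)
    ax.axhline(-np.log10(p_cut), color="red", lw=0.8)
    ax.axvline(lfc_cut, color="grey", lw=0.8, ls="--")
    ax.axvline(-lfc_cut, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("mean log2 fold change")
    ax.set_ylabel("-log10 mean adjusted p")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def similarity_heatmap(matrix: SimilarityMatrix, path,
                       cluster_rows: bool = True) -> None:
    """Standardised pathway x disease heat map.

    Rows are ordered by average-linkage hierarchical clustering on
    Euclidean distance so pathways with similar profiles sit together;
    presentation only, the statistics are untouched.
    """
    data = matrix.standardized.fillna(0.0)
    order = list(range(data.shape[0]))
    if cluster_rows and data.shape[0] > 2:
        linkage = hierarchy.linkage(pdist(data.to_numpy()), method="average")
        order = hierarchy.leaves_list(linkage).tolist()
    data = data.iloc[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * data.shape[1]), max(3, 0.25 * data.shape[0])))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="standardised similarity")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def overlay_figure(overlay: nx.Graph, path) -> None:
    """Spring-layout rendering of a coloured overlay graph."""
    fig, ax = plt.subplots(figsize=(7, 7))
    pos = nx.spring_layout(overlay, seed=0)
    node_colors, node_shapes = [], []
    for _, data in overlay.nodes(data=True):
        key = data.get("complex_consensus", data.get("de_direction", "none"))
        node_colors.append(_NODE_COLORS.get(key, "#cccccc"))
    edge_colors = [_EDGE_COLORS.get(d.get("edge_class", ""), "#cccccc")
                   for _, _, d in overlay.edges(data=True)]
    widths = [2.0 if d.get("edge_class", "").startswith("pathway∩") else 0.8
              for _, _, d in overlay.edges(data=True)]
    nx.draw_networkx(overlay, pos=pos, ax=ax, node_color=node_colors,
                     edge_color=edge_colors, width=widths, node_size=140,
                     font_size=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
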