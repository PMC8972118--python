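"""Minimal plotting of network exports.

Directed networks are drawn on a circular layout with positive edges in
blue and negative edges in red (line width proportional to |weight|);
standardized centralities as a dot plot per group. These are deliberately
plain data exports, not publication styling.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

__all__ = ["plot_network", "plot_centrality"]


def plot_network(network, path, alpha: float = 0.05, title: str | None = None) -> None:
    """Draw the significant edges of a temporal network."""
    from .mlvar import significant_edges

    g = nx.DiGraph()
    g.add_nodes_from(network.node_labels)
    for _, row in significant_edges(network, alpha).iterrows():
        g.add_edge(row["predictor"], row["outcome"], weight=row["weight"])
    pos = nx.circular_layout(g)

    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#f0f0f0", edgecolors="black", node_size=1800)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        nx.draw_networkx_edges(
            g,
            pos,
            edgelist=[(u, v)],
            ax=ax,
            width=1 + 8 * abs(w),
            edge_color="tab:blue" if w > 0 else "tab:red",
            connectionstyle="arc3,rad=0.15",
            arrowsize=12,
        )
    if title:
        ax.set_title(title)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_centrality(centralities: dict, path) -> None:
    """Dot plot of standardized in-/out-strength, one line per group.

    ``centralities`` maps group label -> CentralityTable.
    """
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for which, ax in zip(("in_strength_z", "out_strength_z"), axes):
        for label, cent in centralities.items():
            ax.plot(cent.table[which], cent.table["node"], marker="o", label=label)
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_xlabel(which.replace("_z", " (z)"))
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
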