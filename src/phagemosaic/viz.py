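"""Minimal rendering helpers for the class-domain heatmap and class networks.

Data export is the primary interface; these convenience plots are not meant
to reproduce any publication figure pixel for pixel.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def plot_class_domain_heatmap(matrix: pd.DataFrame, ax=None):
    """Heatmap of the class x domain presence-count matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.35 * matrix.shape[0]))
        )
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="rHMMs with domain")
    return ax


def plot_class_network(graph: nx.Graph, ax=None, seed: int = 0):
    """Spring-layout rendering of a mosaic class network.

    Node size scales with the class architecture count, edge width with the
    number of supporting architecture pairs; contemporary edges are drawn
    darker.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(graph, seed=seed)
    sizes = [60 + 20 * graph.nodes[n].get("n_architectures", 1) for n in graph]
    widths = [1 + d.get("n_arch_pairs", d.get("n_pairs", 1)) / 2 for _, _, d in graph.edges(data=True)]
    colors = [
        "sienna" if d.get("contemporary") else "lightsteelblue"
        for _, _, d in graph.edges(data=True)
    ]
    nx.draw_networkx(
        graph, pos=pos, ax=ax, node_size=sizes, width=widths, edge_color=colors,
        font_size=7,
    )
    ax.set_axis_off()
    return ax
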