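"""Static plot exports: association network, AIC curve, endotype profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402


def plot_network(g, path, seed: int = 0) -> None:
    """Spring-layout rendering; node size by prevalence, edge width by
    co-occurrence count, edge color by capped RR."""
    fig, ax = plt.subplots(figsize=(9, 9))
    pos = nx.spring_layout(g, seed=seed)
    prev = np.array([g.nodes[n].get("prevalence", 1) for n in g.nodes])
    sizes = 100 + 900 * prev / max(prev.max(), 1)
    widths = [0.5 + g.edges[e].get("c_ij", 1) / 50 for e in g.edges]
    colors = [g.edges[e].get("rr_display", 1.0) for e in g.edges]
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, width=widths,
                     edge_color=colors, edge_cmap=plt.cm.viridis,
                     font_size=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_aic_curve(curve, path) -> None:
    fig, ax = plt.subplots()
    ax.plot(curve.k_values, curve.aic_values, "o-")
    if curve.selected_k is not None:
        ax.axvline(curve.selected_k, color="red", ls="--",
                   label=f"selected K = {curve.selected_k}")
        ax.legend()
    ax.set_xlabel("number of classes K")
    ax.set_ylabel("AIC")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_profiles(report, item_names, path) -> None:
    """Mean +/- SD item-response profile per meta-cluster."""
    g = report.n_meta_clusters
    fig, axes = plt.subplots(g, 1, figsize=(10, 2.2 * g), sharex=True,
                             squeeze=False)
    xs = np.arange(len(item_names))
    for i in range(g):
        ax = axes[i, 0]
        ax.bar(xs, report.meta_means[i], yerr=report.meta_sds[i],
               color="steelblue")
        ax.set_ylim(0, 1)
        ax.set_ylabel(f"meta {i}")
    axes[-1, 0].set_xticks(xs)
    axes[-1, 0].set_xticklabels(item_names, rotation=90, fontsize=6)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
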