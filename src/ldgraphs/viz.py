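"""LD-graph layout and plotting.

The layout keeps x = SNP index and chooses y by a deterministic structural
heuristic (magnitude grows with the number of edges strictly spanning a
vertex, sign alternates) followed by left-to-right exponential smoothing.
Vertices with large |y| therefore flag regions of complex structure, while
serial stretches sit on a flat line.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .graphcore import ChromGraph


@dataclass
class Layout:
    x: list[float]
    y: list[float]
    lam: float


@dataclass
class EdgeFrequencyMap:
    p: int
    edges: frozenset[tuple[int, int]]
    freq: dict[tuple[int, int], int]
    n_graphs: int


def layout_graph(g: ChromGraph, lam: float = 0.7) -> Layout:
    if not 0 <= lam < 1:
        raise ValueError("smoothing constant must be in [0, 1)")
    span_count = [0] * (g.p + 2)
    for j, k in g.edges:
        for v in range(j + 1, k):
            span_count[v] += 1
    y0 = [((-1) ** v) * span_count[v] / 2.0 for v in range(1, g.p + 1)]
    y = []
    for i, v in enumerate(y0):
        if i == 0:
            y.append(v)
        else:
            y.append(lam * y[-1] + (1 - lam) * v)
    return Layout([float(i) for i in range(1, g.p + 1)], y, lam)


def plot_ld_graph(g: ChromGraph, layout: Layout, path: str) -> None:
    """Write an image of the graph at the layout coordinates, plus a
    sibling GraphML file carrying x/y attributes for external viewers."""
    if len(layout.x) != g.p:
        raise ValueError("layout does not match graph")
    fig, ax = plt.subplots(figsize=(max(6, g.p / 40), 3))
    for a, b in sorted(g.edges):
        ax.plot(
            [layout.x[a - 1], layout.x[b - 1]],
            [layout.y[a - 1], layout.y[b - 1]],
            color="steelblue",
            linewidth=0.5,
            zorder=1,
        )
    ax.scatter(layout.x, layout.y, s=4, color="black", zorder=2)
    ax.set_xlabel("SNP index")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    G = nx.Graph()
    for v in range(1, g.p + 1):
        G.add_node(v, x=float(layout.x[v - 1]), y=float(layout.y[v - 1]))
    G.add_edges_from(g.edges)
    G.graph["p"] = g.p
    nx.write_graphml(G, str(path) + ".graphml")


def union_graphs(graphs: list[ChromGraph]) -> EdgeFrequencyMap:
    """Union of edge sets with per-edge inclusion counts."""
    if not graphs:
        raise ValueError("need at least one graph")
    p = graphs[0].p
    for g in graphs[1:]:
        if g.p != p:
            raise ValueError(f"vertex counts differ: {g.p} vs {p}")
    freq: dict[tuple[int, int], int] = {}
    for g in graphs:
        for e in g.edges:
            freq[e] = freq.get(e, 0) + 1
    return EdgeFrequencyMap(p, frozenset(freq), freq, len(graphs))


def plot_edge_frequencies(
    fm: EdgeFrequencyMap, layout: Layout, path: str
) -> None:
    """Union-of-graphs display: edges in every graph are black, others are
    interpolated light-to-dark blue by inclusion frequency."""
    fig, ax = plt.subplots(figsize=(max(6, fm.p / 40), 3))
    cmap = plt.get_cmap("Blues")
    for (a, b), k in sorted(fm.freq.items()):
        if k >= fm.n_graphs:
            colour = "black"
        else:
            colour = cmap(0.3 + 0.7 * k / fm.n_graphs)
        ax.plot(
            [layout.x[a - 1], layout.x[b - 1]],
            [layout.y[a - 1], layout.y[b - 1]],
            color=colour,
            linewidth=0.6,
        )
    ax.scatter(layout.x, layout.y, s=4, color="black", zorder=2)
    ax.set_xlabel("SNP index")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(ld: np.ndarray, path: str) -> None:
    """Triangular heatmap of a symmetric pairwise-LD matrix, values
    clipped to [0, 1]."""
    ld = np.asarray(ld, dtype=float)
    if ld.ndim != 2 or ld.shape[0] != ld.shape[1]:
        raise ValueError("pairwise-LD matrix must be square")
    vals = np.clip(ld, 0.0, 1.0)
    mask = np.tril(np.ones_like(vals, dtype=bool), k=-1)
    shown = np.ma.array(vals, mask=mask)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(shown, cmap="Reds", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, shrink=0.8, label="r²")
    ax.set_xlabel("SNP")
    ax.set_ylabel("SNP")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
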