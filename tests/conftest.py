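import itertools

import networkx as nx
import numpy as np
import pytest

from ldgraphs import ChromGraph, MarkerMatrix


def to_networkx(g: ChromGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(1, g.p + 1))
    G.add_edges_from(g.edges)
    return G


def nx_is_chordal(g: ChromGraph) -> bool:
    """Independent chordality oracle (networkx)."""
    return nx.is_chordal(to_networkx(g))


def random_chordal_graph(rng: np.random.Generator, p: int, n_extra: int) -> ChromGraph:
    """Random chordal graph built by adding chordality-preserving edges,
    validated with the networkx oracle (independent of graphcore)."""
    g = ChromGraph(p)
    candidates = list(itertools.combinations(range(1, p + 1), 2))
    added = 0
    order = rng.permutation(len(candidates))
    for k in order:
        if added >= n_extra:
            break
        a, b = candidates[k]
        if g.has_edge(a, b):
            continue
        g2 = g.with_edge(a, b)
        if nx_is_chordal(g2):
            g = g2
            added += 1
    return g


def markov_chain_matrix(
    rng: np.random.Generator, n: int, p: int, flip: float = 0.1
) -> MarkerMatrix:
    """Binary first-order Markov chain: strong serial dependence, exact
    conditional independence of non-adjacent columns given the chain."""
    vals = np.zeros((n, p), dtype=np.int8)
    vals[:, 0] = rng.integers(0, 2, size=n)
    for j in range(1, p):
        flips = rng.random(n) < flip
        vals[:, j] = np.where(flips, 1 - vals[:, j - 1], vals[:, j - 1])
    return MarkerMatrix(vals, "haplotype")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_binary_matrix(rng):
    return MarkerMatrix(
        rng.integers(0, 2, size=(60, 5)).astype(np.int8), "haplotype"
    )
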