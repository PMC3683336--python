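"""Chordal-graph machinery.

Undirected graphs on vertices ``1..p`` (SNP order), chordality testing via
maximum cardinality search (MCS), MCS-based triangulation, clique forests
(junction forests), and the single-edge perturbation tests that a greedy
search over decomposable models needs.

All tie-breaking (MCS vertex choice) is by lowest vertex index, so every
operation here is deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class ChromGraph:
    """Undirected graph on ordered vertices ``1..p``.

    Edges are stored as a frozenset of pairs ``(i, j)`` with ``i < j``.
    Instances are immutable; use :meth:`with_edge` / :meth:`without_edge`
    to derive perturbed graphs.
    """

    __slots__ = ("p", "edges")

    def __init__(self, p: int, edges: Iterable[tuple[int, int]] = ()):
        if p < 0:
            raise ValueError("vertex count must be nonnegative")
        es = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop at vertex {a}")
            if a > b:
                a, b = b, a
            if not (1 <= a and b <= p):
                raise ValueError(f"edge ({a},{b}) outside 1..{p}")
            es.add((a, b))
        object.__setattr__(self, "p", int(p))
        object.__setattr__(self, "edges", frozenset(es))

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("ChromGraph is immutable")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in range(1, self.p + 1)}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def with_edge(self, a: int, b: int) -> "ChromGraph":
        return ChromGraph(self.p, self.edges | {(min(a, b), max(a, b))})

    def without_edge(self, a: int, b: int) -> "ChromGraph":
        e = (min(a, b), max(a, b))
        if e not in self.edges:
            raise ValueError(f"edge {e} not present")
        return ChromGraph(self.p, self.edges - {e})

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ChromGraph)
            and self.p == other.p
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.p, self.edges))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ChromGraph(p={self.p}, n_edges={len(self.edges)})"


@dataclass
class CliqueForest:
    """Cliques, junction-forest edges and separators of a chordal graph.

    ``tree_edges[k]`` joins ``cliques[tree_edges[k][0]]`` and
    ``cliques[tree_edges[k][1]]``; ``separators[k]`` is their intersection.
    One tree per connected component.
    """

    cliques: list[frozenset[int]]
    tree_edges: list[tuple[int, int]] = field(default_factory=list)
    separators: list[frozenset[int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.tree_edges) != len(self.separators):
            raise ValueError("one separator per tree edge required")


# ---------------------------------------------------------------------------
# Maximum cardinality search


def _mcs_order(adj: dict[int, set[int]], p: int):
    """MCS visit order with lowest-index tie-breaking.

    Returns ``(order, earlier)`` where ``earlier[v]`` is the set of
    neighbours of ``v`` visited before ``v``.
    """
    label = {v: 0 for v in range(1, p + 1)}
    visited = [False] * (p + 1)
    heap = [(0, v) for v in range(1, p + 1)]
    heapq.heapify(heap)
    order: list[int] = []
    earlier: dict[int, set[int]] = {}
    while heap:
        neg, v = heapq.heappop(heap)
        if visited[v] or -neg != label[v]:
            continue
        visited[v] = True
        order.append(v)
        earlier[v] = {u for u in adj[v] if visited[u]}
        for u in adj[v]:
            if not visited[u]:
                label[u] += 1
                heapq.heappush(heap, (-label[u], u))
    return order, earlier


def is_chordal(g: ChromGraph) -> bool:
    """True iff ``g`` has no chordless cycle of length >= 4."""
    adj = g.adjacency()
    order, earlier = _mcs_order(adj, g.p)
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        ev = earlier[v]
        if len(ev) <= 1:
            continue
        u = max(ev, key=pos.__getitem__)
        if not (ev - {u}) <= adj[u]:
            return False
    return True


def mcs_triangulate(g: ChromGraph) -> tuple[ChromGraph, frozenset[tuple[int, int]]]:
    """Triangulate by the elimination game along the reverse MCS order.

    If ``g`` is already chordal the reverse MCS order is a perfect
    elimination ordering and no fill edges are produced.
    """
    adj = {v: set(nbrs) for v, nbrs in g.adjacency().items()}
    order, _ = _mcs_order(adj, g.p)
    fills: set[tuple[int, int]] = set()
    eliminated = [False] * (g.p + 1)
    for v in reversed(order):
        nbrs = sorted(u for u in adj[v] if not eliminated[u])
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                if b not in adj[a]:
                    adj[a].add(b)
                    adj[b].add(a)
                    fills.add((a, b))
        eliminated[v] = True
    return ChromGraph(g.p, set(g.edges) | fills), frozenset(fills)


def clique_forest(g: ChromGraph) -> CliqueForest:
    """Maximal cliques and a junction forest of a chordal graph.

    Blair-Peyton construction along the MCS order: a clique is completed
    whenever the cardinality label fails to increase, at which point the
    new clique hangs off the representative clique of the last-visited
    vertex of its separator.
    """
    if not is_chordal(g):
        raise ValueError("clique forest requires a chordal graph")
    adj = g.adjacency()
    order, earlier = _mcs_order(adj, g.p)
    pos = {v: i for i, v in enumerate(order)}

    cliques: list[set[int]] = []
    tree_edges: list[tuple[int, int]] = []
    separators: list[frozenset[int]] = []
    clique_of: dict[int, int] = {}
    current: set[int] | None = None
    prev_card = -1
    for v in order:
        card = len(earlier[v])
        if current is None:
            current = {v}
        elif card > prev_card:
            current.add(v)
        else:
            cliques.append(current)
            idx = len(cliques)  # index the new current clique will get
            sep = earlier[v]
            current = set(sep) | {v}
            if sep:
                u = max(sep, key=pos.__getitem__)
                tree_edges.append((idx, clique_of[u]))
                separators.append(frozenset(sep))
        clique_of[v] = len(cliques)
        prev_card = card
    if current is not None:
        cliques.append(current)
    return CliqueForest(
        [frozenset(c) for c in cliques], tree_edges, separators
    )


# ---------------------------------------------------------------------------
# Single-edge perturbations

# For a chordal graph and non-adjacent a, b in the same component,
# G + (a,b) is chordal iff the common neighbourhood N(a) & N(b) separates
# a from b; the (then complete) common neighbourhood is the S of the unique
# new clique {a,b} | S.  In different components the edge is always addable
# with S empty.


def _separates(adj: dict[int, set[int]], S: set[int], a: int, b: int) -> bool:
    """True iff removing S disconnects a from b (early exit on reaching b)."""
    seen = set(S)
    seen.add(a)
    stack = [a]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u == b:
                return False
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return True


def edge_addable(
    g: ChromGraph, f: CliqueForest | None, a: int, b: int
) -> tuple[bool, frozenset[int] | None]:
    """Can (a,b) be added while staying chordal?  Returns (ok, separator)."""
    if a == b:
        raise ValueError("no self-loops")
    if g.has_edge(a, b):
        raise ValueError(f"edge ({a},{b}) already present")
    adj = g.adjacency()
    S = adj[a] & adj[b]
    if _separates(adj, S, a, b):
        return True, frozenset(S)
    return False, None


def edge_removable(
    g: ChromGraph, f: CliqueForest | None, a: int, b: int
) -> tuple[bool, frozenset[int] | None]:
    """Can (a,b) be removed while staying chordal?

    True iff (a,b) lies in exactly one clique C, i.e. the common
    neighbourhood of a and b is complete; then ``S = C - {a,b}``.
    """
    if not g.has_edge(a, b):
        raise ValueError(f"edge ({a},{b}) not present")
    adj = g.adjacency()
    S = adj[a] & adj[b]
    ss = sorted(S)
    for i, u in enumerate(ss):
        for v in ss[i + 1 :]:
            if v not in adj[u]:
                return False, None
    return True, frozenset(S)


def connected_components(g: ChromGraph) -> list[set[int]]:
    """Partition of 1..p into components, ordered by smallest member."""
    adj = g.adjacency()
    seen = [False] * (g.p + 1)
    comps: list[set[int]] = []
    for v in range(1, g.p + 1):
        if seen[v]:
            continue
        comp = {v}
        seen[v] = True
        stack = [v]
        while stack:
            w = stack.pop()
            for u in adj[w]:
                if not seen[u]:
                    seen[u] = True
                    comp.add(u)
                    stack.append(u)
        comps.append(comp)
    return comps


def boundary(g: ChromGraph, A: Iterable[int]) -> set[int]:
    """bd(A) = {v : v ~ w for some w in A} - A."""
    A = set(A)
    bad = [v for v in A if not 1 <= v <= g.p]
    if bad:
        raise ValueError(f"vertices {bad} outside 1..{g.p}")
    adj = g.adjacency()
    out: set[int] = set()
    for w in A:
        out |= adj[w]
    return out - A
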