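"""Greedy model search over decomposable graphs.

The standard route starts from the *skeleton* (edges between physically
adjacent SNPs), greedily adds the single decomposability-preserving edge
with the largest IC reduction until none improves, then prunes edges (the
skeleton included) in the same greedy fashion.

The fast route fits blocks of ``L`` SNPs with overlap ``K`` independently,
stitches consecutive block models with the m* rule (drop cumulative edges
reaching past m*, take block edges reaching beyond it), triangulates the
result with MCS, and prunes.  Runtime is linear in p at fixed N.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable

from .data_io import MarkerMatrix
from .graphcore import (
    ChromGraph,
    CliqueForest,
    _separates,
    clique_forest,
    is_chordal,
    mcs_triangulate,
)
from .scoring import NOMINAL, ModelScore, ScoreDelta, delta_score, model_score

TraceStep = namedtuple("TraceStep", ["edge", "direction", "delta"])

AIC = "aic"
BIC = "bic"


@dataclass
class SelectionConfig:
    """Search configuration.  ``criterion`` resolves the penalty: aic -> 2,
    bic -> ln(N); an explicit ``alpha`` overrides both."""

    criterion: str = BIC
    alpha: float | None = None
    dim_mode: str = NOMINAL
    protect_skeleton_forward: bool = True
    max_span: int | None = None

    def resolve_alpha(self, n_rows: int) -> float:
        if self.alpha is not None:
            if self.alpha <= 0:
                raise ValueError("alpha must be positive")
            return float(self.alpha)
        if self.criterion == AIC:
            return 2.0
        if self.criterion == BIC:
            return math.log(n_rows)
        raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class FastConfig:
    L: int = 100
    K: int = 20

    def __post_init__(self):
        if not 0 < self.K < self.L:
            raise ValueError("require 0 < K < L")


@dataclass
class FitResult:
    graph: ChromGraph
    forest: CliqueForest
    score: ModelScore
    trace: list[TraceStep] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class StitchState:
    cum_edges: set[tuple[int, int]]
    e: int
    m_star: int | None = None
    violated: bool = False
    warnings: list[str] = field(default_factory=list)


def skeleton(p: int) -> ChromGraph:
    """Edges between physically adjacent SNPs: (i, i+1) for i < p."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return ChromGraph(p, [(i, i + 1) for i in range(1, p)])


# ---------------------------------------------------------------------------
# Greedy engine


def _components_of(adj: dict[int, set[int]], p: int) -> list[int]:
    """Component label per vertex (index 1..p)."""
    label = [0] * (p + 1)
    nxt = 0
    for v in range(1, p + 1):
        if label[v]:
            continue
        nxt += 1
        label[v] = nxt
        stack = [v]
        while stack:
            w = stack.pop()
            for u in adj[w]:
                if not label[u]:
                    label[u] = nxt
                    stack.append(u)
    return label


def _cached_delta(cache, m, a, b, S, alpha, direction, mode) -> ScoreDelta:
    key = (a, b, tuple(sorted(S)), direction, mode)
    d = cache.get(key)
    if d is None:
        d = delta_score(m, None, a, b, S, alpha, direction=direction, mode=mode)
        cache[key] = d
    return d


def forward_search(
    m: MarkerMatrix,
    g0: ChromGraph,
    cfg: SelectionConfig | None = None,
    _cache: dict | None = None,
) -> FitResult:
    """Greedy forward search from chordal ``g0``.

    At each step the addable edge with the most negative IC change is added
    (ties broken by lexicographically smallest (i, j)); the search stops
    when no addable edge improves the criterion.  Edges of ``g0`` are never
    removed here.
    """
    cfg = cfg or SelectionConfig()
    if not is_chordal(g0):
        raise ValueError("forward search requires a chordal start graph")
    if g0.p != m.p:
        raise ValueError(f"graph has {g0.p} vertices but data has {m.p} columns")
    alpha = cfg.resolve_alpha(m.n_rows)
    cache = _cache if _cache is not None else {}
    p = g0.p
    adj = g0.adjacency()
    edges = set(g0.edges)
    trace: list[TraceStep] = []

    while True:
        comp = _components_of(adj, p)
        n_comp = max(comp[1:]) if p else 0
        cand: set[tuple[int, int]] = set()
        for v in range(1, p + 1):
            ns = sorted(adj[v])
            for i, a in enumerate(ns):
                for b in ns[i + 1 :]:
                    if (a, b) not in edges:
                        cand.add((a, b))
        if n_comp > 1:
            by_comp: dict[int, list[int]] = {}
            for v in range(1, p + 1):
                by_comp.setdefault(comp[v], []).append(v)
            comps = sorted(by_comp.values(), key=lambda c: c[0])
            for i, ca in enumerate(comps):
                for cb in comps[i + 1 :]:
                    for a in ca:
                        for b in cb:
                            cand.add((min(a, b), max(a, b)))
        best: tuple[int, int] | None = None
        best_delta: ScoreDelta | None = None
        for a, b in sorted(cand):
            if cfg.max_span is not None and b - a > cfg.max_span:
                continue
            S = adj[a] & adj[b]
            if comp[a] == comp[b]:
                if not _separates(adj, S, a, b):
                    continue
            d = _cached_delta(cache, m, a, b, S, alpha, "add", cfg.dim_mode)
            if d.d_ic < 0 and (best_delta is None or d.d_ic < best_delta.d_ic):
                best, best_delta = (a, b), d
        if best is None:
            break
        a, b = best
        edges.add((a, b))
        adj[a].add(b)
        adj[b].add(a)
        trace.append(TraceStep((a, b), "add", best_delta))

    graph = ChromGraph(p, edges)
    forest = clique_forest(graph)
    score = model_score(m, forest, alpha, mode=cfg.dim_mode)
    return FitResult(graph, forest, score, trace, [])


def backward_prune(
    m: MarkerMatrix,
    g: ChromGraph,
    cfg: SelectionConfig | None = None,
    _cache: dict | None = None,
) -> FitResult:
    """Greedy backward pruning: repeatedly remove the removable edge with
    the most negative IC change; skeleton edges are *not* protected."""
    cfg = cfg or SelectionConfig()
    if not is_chordal(g):
        raise ValueError("backward pruning requires a chordal graph")
    if g.p != m.p:
        raise ValueError(f"graph has {g.p} vertices but data has {m.p} columns")
    alpha = cfg.resolve_alpha(m.n_rows)
    cache = _cache if _cache is not None else {}
    adj = g.adjacency()
    edges = set(g.edges)
    trace: list[TraceStep] = []

    while True:
        best: tuple[int, int] | None = None
        best_delta: ScoreDelta | None = None
        for a, b in sorted(edges):
            S = adj[a] & adj[b]
            ss = sorted(S)
            complete = all(
                v in adj[u] for i, u in enumerate(ss) for v in ss[i + 1 :]
            )
            if not complete:
                continue
            d = _cached_delta(cache, m, a, b, S, alpha, "remove", cfg.dim_mode)
            if d.d_ic < 0 and (best_delta is None or d.d_ic < best_delta.d_ic):
                best, best_delta = (a, b), d
        if best is None:
            break
        a, b = best
        edges.remove((a, b))
        adj[a].remove(b)
        adj[b].remove(a)
        trace.append(TraceStep((a, b), "remove", best_delta))

    graph = ChromGraph(g.p, edges)
    forest = clique_forest(graph)
    score = model_score(m, forest, alpha, mode=cfg.dim_mode)
    return FitResult(graph, forest, score, trace, [])


def _check_drift(
    m: MarkerMatrix,
    cfg: SelectionConfig,
    start: ChromGraph,
    result: FitResult,
) -> None:
    """Guard against incremental-score drift: the start IC plus the traced
    deltas must match the recomputed final IC (nominal mode; in observed
    mode dimension deltas need not telescope, so only warn)."""
    alpha = cfg.resolve_alpha(m.n_rows)
    ic0 = model_score(m, clique_forest(start), alpha, mode=cfg.dim_mode).ic
    tracked = ic0 + sum(step.delta.d_ic for step in result.trace)
    drift = abs(tracked - result.score.ic)
    tol = 1e-6 * max(1.0, abs(result.score.ic))
    if drift > tol:
        msg = (
            f"incremental IC {tracked:.6f} differs from recomputed "
            f"{result.score.ic:.6f} (drift {drift:.2e})"
        )
        if cfg.dim_mode == NOMINAL:
            raise RuntimeError(msg)
        result.warnings.append(msg)


def fit_standard(m: MarkerMatrix, cfg: SelectionConfig | None = None) -> FitResult:
    """Forward search from the skeleton followed by backward pruning."""
    cfg = cfg or SelectionConfig()
    cache: dict = {}
    g0 = skeleton(m.p)
    fwd = forward_search(m, g0, cfg, _cache=cache)
    bwd = backward_prune(m, fwd.graph, cfg, _cache=cache)
    res = FitResult(
        bwd.graph,
        bwd.forest,
        bwd.score,
        fwd.trace + bwd.trace,
        fwd.warnings + bwd.warnings,
    )
    _check_drift(m, cfg, g0, res)
    return res


# ---------------------------------------------------------------------------
# Fast blockwise algorithm


def block_bounds(p: int, fc: FastConfig | None = None) -> list[tuple[int, int]]:
    """1-based inclusive block spans: block i covers
    [(i-1)(L-K)+1, (i-1)(L-K)+L], clipped at p; generation stops once a
    block reaches p, and a final block of length <= K merges into the
    previous one."""
    fc = fc or FastConfig()
    if p < 1:
        raise ValueError("p must be >= 1")
    bounds: list[tuple[int, int]] = []
    i = 0
    while True:
        start = i * (fc.L - fc.K) + 1
        end = min(start + fc.L - 1, p)
        if bounds and end - start + 1 <= fc.K:
            s0, _ = bounds[-1]
            bounds[-1] = (s0, p)
            break
        bounds.append((start, end))
        if end >= p:
            break
        i += 1
    return bounds


def stitch(
    state: StitchState,
    block_edges: Iterable[tuple[int, int]],
    block_start: int,
    block_end: int,
    cum_end: int,
    K: int | None = None,
) -> StitchState:
    """Fold one block model into the cumulative graph with the m* rule.

    m* is the largest right endpoint among cumulative edges whose left
    endpoint precedes the overlap; cumulative edges reaching past m* are
    dropped and block edges reaching beyond it are taken instead.  If m*
    reaches the left end of a block edge extending past the old cumulative
    end, the overlap was too small and a warning is recorded.
    """
    if cum_end != state.e:
        raise ValueError(f"cum_end {cum_end} does not match state.e {state.e}")
    if K is not None and block_start != state.e - K + 1:
        raise ValueError(
            f"block must start at e-K+1 = {state.e - K + 1}, got {block_start}"
        )
    block_edges = {(min(a, b), max(a, b)) for a, b in block_edges}
    for a, b in block_edges:
        if a < block_start or b > block_end:
            raise ValueError(f"block edge ({a},{b}) outside [{block_start},{block_end}]")
    s = block_start
    left_ws = [w for v, w in state.cum_edges if v <= s - 1]
    m_star = max(left_ws) if left_ws else s - 1
    new_cum = {(v, w) for v, w in state.cum_edges if w <= m_star}
    new_cum |= {(v, w) for v, w in block_edges if w > m_star}
    beyond = [v for v, w in block_edges if w >= state.e + 1]
    violated = bool(beyond) and m_star >= min(beyond)
    warnings = list(state.warnings)
    if violated:
        warnings.append(
            f"stitch overlap too small at block [{block_start},{block_end}]: "
            f"m*={m_star} >= min left endpoint {min(beyond)} of an edge "
            "extending past the previous blocks"
        )
    return StitchState(new_cum, block_end, m_star, violated, warnings)


def fast_forward(
    m: MarkerMatrix,
    cfg: SelectionConfig | None = None,
    fc: FastConfig | None = None,
) -> tuple[ChromGraph, list[str]]:
    """Blockwise forward search: fit each block from its internal skeleton,
    left-fold through :func:`stitch`, then MCS-triangulate."""
    cfg = cfg or SelectionConfig()
    fc = fc or FastConfig()
    bounds = block_bounds(m.p, fc)
    block_graphs: list[set[tuple[int, int]]] = []
    for s, e in bounds:
        sub = m.select(list(range(s, e + 1)))
        res = forward_search(sub, skeleton(sub.p), cfg)
        block_graphs.append(
            {(a + s - 1, b + s - 1) for a, b in res.graph.edges}
        )
    state = StitchState(block_graphs[0], bounds[0][1])
    for (s, e), bedges in zip(bounds[1:], block_graphs[1:]):
        state = stitch(state, bedges, s, e, state.e)
    graph = ChromGraph(m.p, state.cum_edges)
    tri, fills = mcs_triangulate(graph)
    warnings = list(state.warnings)
    if fills:
        warnings.append(f"triangulation added {len(fills)} fill edge(s)")
    return tri, warnings


def fit_fast(
    m: MarkerMatrix,
    cfg: SelectionConfig | None = None,
    fc: FastConfig | None = None,
) -> FitResult:
    """Fast forward phase followed by backward pruning."""
    cfg = cfg or SelectionConfig()
    graph, warnings = fast_forward(m, cfg, fc)
    res = backward_prune(m, graph, cfg)
    res.warnings = warnings + res.warnings
    return res
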