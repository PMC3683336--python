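"""Fitting clique-marginal models, sampling via the junction forest,
random LD-like generators, and true-vs-estimated graph comparison."""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import GENOTYPE, HAPLOTYPE, MarkerMatrix
from .graphcore import ChromGraph, CliqueForest, clique_forest, edge_addable
from .scoring import count_table, decomposable_loglik
from .selection import skeleton

_CODES = {HAPLOTYPE: (0, 1), GENOTYPE: (0, 1, 2)}


@dataclass
class FittedModel:
    """A decomposable model: clique forest plus clique-marginal tables.

    ``tables[i]`` maps configurations of ``clique_vars[i]`` (sorted vertex
    order) to probabilities summing to 1.  Adjacent clique tables agree on
    their separator margin.
    """

    forest: CliqueForest
    clique_vars: list[tuple[int, ...]]
    tables: list[dict[tuple[int, ...], float]]
    p: int
    kind: str = HAPLOTYPE

    def __post_init__(self):
        for t in self.tables:
            s = sum(t.values())
            if abs(s - 1.0) > 1e-8:
                raise ValueError(f"clique table sums to {s}, not 1")
        _assert_consistent(self)


@dataclass
class GeneratorConfig:
    """Random-model generator settings.

    ``dirichlet_conc`` is the base concentration of the table draws;
    ``ld_strength`` adds weight to one anchor cell per conditional row
    (anchors cycle across separator configurations), which keeps the
    dependence carried by each generated edge strong enough to be
    detectable at realistic sample sizes.  ``ld_strength=0`` falls back to
    plain symmetric Dirichlet draws.
    """

    p: int
    n_extra: int = 0
    max_width: int = 5
    dirichlet_conc: float = 1.0
    seed: int = 0
    kind: str = HAPLOTYPE
    ld_strength: float = 3.0

    def __post_init__(self):
        if self.max_width < 2:
            raise ValueError("max_width must be >= 2")
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")
        if self.ld_strength < 0:
            raise ValueError("ld_strength must be >= 0")


@dataclass
class ComparisonResult:
    undershoot: int
    overshoot: int
    fnr: float
    fir: float


def _margin(
    vars: tuple[int, ...], table: dict[tuple[int, ...], float], sub: tuple[int, ...]
) -> dict[tuple[int, ...], float]:
    idx = [vars.index(v) for v in sub]
    out: dict[tuple[int, ...], float] = {}
    for cfg, pr in table.items():
        key = tuple(cfg[i] for i in idx)
        out[key] = out.get(key, 0.0) + pr
    return out


def _assert_consistent(model: FittedModel, tol: float = 1e-8) -> None:
    for (i, j), sep in zip(model.forest.tree_edges, model.forest.separators):
        sub = tuple(sorted(sep))
        mi = _margin(model.clique_vars[i], model.tables[i], sub)
        mj = _margin(model.clique_vars[j], model.tables[j], sub)
        for key in set(mi) | set(mj):
            if abs(mi.get(key, 0.0) - mj.get(key, 0.0)) > tol:
                raise AssertionError(
                    f"separator margin mismatch on {sub} at config {key}"
                )


def fit_model(m: MarkerMatrix, f: CliqueForest) -> FittedModel:
    """Maximum-likelihood clique tables: empirical counts divided by N."""
    if m.n_rows == 0:
        raise ValueError("cannot fit a model to zero rows")
    clique_vars = [tuple(sorted(c)) for c in f.cliques]
    tables = []
    for vars in clique_vars:
        ct = count_table(m, vars)
        tables.append({cfg: c / m.n_rows for cfg, c in ct.cells.items()})
    return FittedModel(f, clique_vars, tables, m.p, m.kind)


def _forest_traversal(model: FittedModel):
    """Yield (clique index, parent index or None) in a deterministic order,
    each tree rooted at the clique containing its lowest vertex."""
    n = len(model.clique_vars)
    nbrs: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in model.forest.tree_edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    seen = [False] * n
    order = []
    for root in sorted(range(n), key=lambda i: min(model.clique_vars[i])):
        if seen[root]:
            continue
        seen[root] = True
        stack = [(root, None)]
        while stack:
            i, par = stack.pop()
            order.append((i, par))
            for j in sorted(nbrs[i], reverse=True):
                if not seen[j]:
                    seen[j] = True
                    stack.append((j, i))
    return order


def sample(model: FittedModel, n: int, seed: int = 0) -> MarkerMatrix:
    """Draw ``n`` observations: the root clique of each junction tree from
    its table, then each child clique's non-separator vertices from the
    conditional given the separator.  Reproducible given ``seed``."""
    rng = np.random.default_rng(seed)
    values = np.zeros((n, model.p), dtype=np.int8)
    for i, par in _forest_traversal(model):
        vars = model.clique_vars[i]
        table = model.tables[i]
        cfgs = sorted(table)
        probs = np.array([table[c] for c in cfgs], dtype=float)
        probs /= probs.sum()
        if par is None:
            idx = rng.choice(len(cfgs), size=n, p=probs)
            for k, v in enumerate(vars):
                values[:, v - 1] = [cfgs[t][k] for t in idx]
            continue
        sep = tuple(sorted(set(vars) & set(model.clique_vars[par])))
        res = tuple(v for v in vars if v not in sep)
        sep_pos = [vars.index(v) for v in sep]
        res_pos = [vars.index(v) for v in res]
        cond: dict[tuple[int, ...], tuple[list, np.ndarray]] = {}
        for cfg, pr in sorted(table.items()):
            skey = tuple(cfg[q] for q in sep_pos)
            rkey = tuple(cfg[q] for q in res_pos)
            cond.setdefault(skey, ([], []))[0].append(rkey)
            cond[skey][1].append(pr)
        sep_cols = values[:, [v - 1 for v in sep]]
        row_keys = [tuple(int(x) for x in r) for r in sep_cols]
        uniq = sorted(set(row_keys))
        key_to_rows: dict[tuple[int, ...], list[int]] = {k: [] for k in uniq}
        for r, k in enumerate(row_keys):
            key_to_rows[k].append(r)
        for skey in uniq:
            if skey not in cond:
                raise AssertionError(
                    f"separator configuration {skey} has zero probability"
                )
            rkeys, prs = cond[skey]
            prs = np.asarray(prs, dtype=float)
            prs = prs / prs.sum()
            rows = key_to_rows[skey]
            draw = rng.choice(len(rkeys), size=len(rows), p=prs)
            for r, t in zip(rows, draw):
                for k, v in enumerate(res):
                    values[r, v - 1] = rkeys[t][k]
    return MarkerMatrix(values, model.kind)


def random_ld_model(cfg: GeneratorConfig) -> tuple[ChromGraph, FittedModel, list[str]]:
    """Random sparse decomposable model containing the serial skeleton.

    Extra edges (i, j) with 2 <= j-i <= max_width are accepted only when
    chordality is preserved.  Clique tables are generated root-to-leaf
    along the junction forest from symmetric Dirichlet draws, which makes
    separator margins consistent by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    g = skeleton(cfg.p)
    warnings: list[str] = []
    placed = 0
    attempts = 0
    max_attempts = 200 * max(cfg.n_extra, 1) + 1000
    while placed < cfg.n_extra and attempts < max_attempts:
        attempts += 1
        span = int(rng.integers(2, cfg.max_width + 1))
        if span >= cfg.p:
            continue
        i = int(rng.integers(1, cfg.p - span + 1))
        j = i + span
        if g.has_edge(i, j):
            continue
        ok, _ = edge_addable(g, None, i, j)
        if ok:
            g = g.with_edge(i, j)
            placed += 1
    if placed < cfg.n_extra:
        warnings.append(
            f"placed only {placed} of {cfg.n_extra} extra edges "
            f"after {attempts} attempts"
        )

    forest = clique_forest(g)
    clique_vars = [tuple(sorted(c)) for c in forest.cliques]
    codes = _CODES[cfg.kind]
    tables: list[dict[tuple[int, ...], float] | None] = [None] * len(clique_vars)

    # reuse the sampling traversal: roots get full Dirichlet tables,
    # children get Dirichlet conditionals glued to the parent's separator
    # margin
    model_stub = FittedModel.__new__(FittedModel)
    model_stub.forest = forest
    model_stub.clique_vars = clique_vars
    for i, par in _forest_traversal(model_stub):
        vars = clique_vars[i]
        all_cfgs = list(itertools.product(codes, repeat=len(vars)))
        if par is None:
            probs = rng.dirichlet([cfg.dirichlet_conc] * len(all_cfgs))
            tables[i] = dict(zip(all_cfgs, probs.tolist()))
            continue
        sep = tuple(sorted(set(vars) & set(clique_vars[par])))
        res = tuple(v for v in vars if v not in sep)
        sep_margin = _margin(clique_vars[par], tables[par], sep)
        res_cfgs = list(itertools.product(codes, repeat=len(res)))
        table: dict[tuple[int, ...], float] = {}
        shift = int(rng.integers(len(res_cfgs)))
        for t, skey in enumerate(sorted(itertools.product(codes, repeat=len(sep)))):
            weights = [cfg.dirichlet_conc] * len(res_cfgs)
            weights[(t + shift) % len(res_cfgs)] += cfg.ld_strength
            cond = rng.dirichlet(weights)
            base = sep_margin.get(skey, 0.0)
            for rkey, pr in zip(res_cfgs, cond.tolist()):
                full = dict(zip(sep, skey)) | dict(zip(res, rkey))
                key = tuple(full[v] for v in vars)
                table[key] = base * pr
        tables[i] = table
    model = FittedModel(forest, clique_vars, tables, cfg.p, cfg.kind)
    return g, model, warnings


def compare_graphs(true_g: ChromGraph, est_g: ChromGraph) -> ComparisonResult:
    """Undershoot (missed true edges), overshoot (extra estimated edges)
    and the corresponding rates, both normalized by the number of true
    edges."""
    if true_g.p != est_g.p:
        raise ValueError(
            f"vertex counts differ: true has p={true_g.p}, estimate p={est_g.p}"
        )
    under = len(true_g.edges - est_g.edges)
    over = len(est_g.edges - true_g.edges)
    n_true = len(true_g.edges)
    fnr = under / n_true if n_true else 0.0
    fir = over / n_true if n_true else 0.0
    return ComparisonResult(under, over, fnr, fir)


def mean_rates(
    undershoots: list[int], overshoots: list[int], n_true_edges: int
) -> tuple[float, float]:
    """Average edgewise false-negative / false-inclusion rates across
    replicate comparisons sharing one generating graph."""
    results = [
        ComparisonResult(u, o, u / n_true_edges, o / n_true_edges)
        for u, o in zip(undershoots, overshoots, strict=True)
    ]
    fnr = sum(r.fnr for r in results) / len(results)
    fir = sum(r.fir for r in results) / len(results)
    return fnr, fir


def diploid_from_haplotypes(h: MarkerMatrix) -> MarkerMatrix:
    """Sum consecutive haplotype row pairs into genotype rows.  The reverse
    direction (splitting genotypes into haplotypes) is not defined."""
    if h.kind != HAPLOTYPE:
        raise ValueError("input must be haplotype data")
    if h.n_rows % 2:
        raise ValueError("haplotype row count must be even")
    vals = h.values[0::2] + h.values[1::2]
    return MarkerMatrix(vals.astype(np.int8), GENOTYPE, list(h.marker_ids), h.positions)


# ---------------------------------------------------------------------------
# Plain-text model serialization (for the CLI)


def save_model(model: FittedModel, path: str) -> None:
    doc = {
        "p": model.p,
        "kind": model.kind,
        "cliques": [list(v) for v in model.clique_vars],
        "tree_edges": [list(e) for e in model.forest.tree_edges],
        "separators": [sorted(s) for s in model.forest.separators],
        "tables": [
            {",".join(map(str, cfg)): pr for cfg, pr in sorted(t.items())}
            for t in model.tables
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> FittedModel:
    with open(path) as fh:
        doc = json.load(fh)
    forest = CliqueForest(
        [frozenset(c) for c in doc["cliques"]],
        [tuple(e) for e in doc["tree_edges"]],
        [frozenset(s) for s in doc["separators"]],
    )
    clique_vars = [tuple(c) for c in doc["cliques"]]
    tables = [
        {tuple(int(t) for t in cfg.split(",")): pr for cfg, pr in table.items()}
        for table in doc["tables"]
    ]
    return FittedModel(forest, clique_vars, tables, doc["p"], doc["kind"])
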