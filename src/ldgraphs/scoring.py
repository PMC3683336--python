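"""Likelihood, dimension and single-edge score deltas for decomposable models.

Everything is in natural logarithms; the information criterion is
``IC(G) = -2 * loglik + alpha * dim(G)`` with ``alpha = 2`` (AIC) or
``alpha = ln N`` (BIC).

The deviance change of a single-edge move with separator S is
``-/+ 2 N * I(a; b | S)`` (empirical conditional mutual information), and
the nominal dimension change is ``(r_a - 1)(r_b - 1) * prod_{s in S} r_s``
with ``r_v`` the number of distinct observed codes of column v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import MarkerMatrix
from .graphcore import CliqueForest

NOMINAL = "nominal"
OBSERVED = "observed"


@dataclass
class CountTable:
    vars: tuple[int, ...]
    cells: dict[tuple[int, ...], int]
    total: int


@dataclass
class ModelScore:
    loglik: float
    dim: int
    alpha: float

    @property
    def ic(self) -> float:
        return -2.0 * self.loglik + self.alpha * self.dim


@dataclass
class ScoreDelta:
    d_deviance: float
    d_dim: int
    alpha: float
    separator: frozenset[int]

    @property
    def d_ic(self) -> float:
        return self.d_deviance + self.alpha * self.d_dim


# ---------------------------------------------------------------------------
# Keyed counting (codes are always in 0..2, so radix 3 per column)

_RADIX = 3


def _keys(values: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    """Integer key per row over the given 1-based columns."""
    n = values.shape[0]
    if len(cols) == 0:
        return np.zeros(n, dtype=np.int64)
    sub = values[:, [c - 1 for c in cols]].astype(np.int64)
    if len(cols) <= 39:
        weights = _RADIX ** np.arange(len(cols), dtype=np.int64)
        return sub @ weights
    _, inv = np.unique(sub, axis=0, return_inverse=True)
    return inv.astype(np.int64)


def _n_observed(values: np.ndarray, cols: Sequence[int]) -> int:
    if len(cols) == 0:
        return 1
    return len(np.unique(_keys(values, cols)))


def count_table(m: MarkerMatrix, vars: Sequence[int]) -> CountTable:
    """Exact joint counts over the listed 1-based columns (order-sensitive)."""
    vars = tuple(vars)
    if not vars:
        raise ValueError("vars must be nonempty")
    if len(set(vars)) != len(vars):
        raise ValueError("vars must be distinct")
    for v in vars:
        if not 1 <= v <= m.p:
            raise ValueError(f"variable {v} outside 1..{m.p}")
    sub = m.values[:, [v - 1 for v in vars]]
    uniq, counts = np.unique(sub, axis=0, return_counts=True)
    cells = {tuple(int(x) for x in row): int(c) for row, c in zip(uniq, counts)}
    return CountTable(vars, cells, m.n_rows)


def _entropy_term(values: np.ndarray, cols: Sequence[int], log_n: float) -> float:
    """sum over observed cells of n * (ln n - ln N)."""
    if len(cols) == 0:
        return 0.0
    _, counts = np.unique(_keys(values, cols), return_counts=True)
    return float(np.sum(counts * (np.log(counts) - log_n)))


def decomposable_loglik(m: MarkerMatrix, f: CliqueForest) -> float:
    """Maximized log-likelihood of the decomposable model with clique
    forest ``f``: clique terms minus separator terms, with 0 ln 0 = 0."""
    for c in f.cliques:
        for v in c:
            if not 1 <= v <= m.p:
                raise ValueError(f"clique vertex {v} outside 1..{m.p}")
    log_n = math.log(m.n_rows)
    ll = 0.0
    for c in f.cliques:
        ll += _entropy_term(m.values, sorted(c), log_n)
    for s in f.separators:
        ll -= _entropy_term(m.values, sorted(s), log_n)
    return ll


def model_dimension(
    f: CliqueForest,
    levels: Sequence[int] | np.ndarray | dict[int, int],
    mode: str = NOMINAL,
    m: MarkerMatrix | None = None,
) -> int:
    """Number of free parameters of the decomposable model.

    nominal: sum over cliques of (prod r_v - 1) minus the same over
    separators.  observed: each product of level counts is replaced by the
    number of distinct observed configurations of that vertex set
    (requires ``m``).
    """
    if mode == OBSERVED:
        if m is None:
            raise ValueError("mode='observed' requires the data matrix")
        size = lambda vs: _n_observed(m.values, sorted(vs))
    elif mode == NOMINAL:
        if isinstance(levels, dict):
            r = levels
        else:
            r = {v + 1: int(levels[v]) for v in range(len(levels))}
        if any(x < 1 for x in r.values()):
            raise ValueError("level counts must be >= 1")
        size = lambda vs: math.prod(r[v] for v in vs)
    else:
        raise ValueError(f"unknown dimension mode {mode!r}")
    dim = sum(size(c) - 1 for c in f.cliques)
    dim -= sum(size(s) - 1 for s in f.separators)
    return int(dim)


def cmi(m: MarkerMatrix, a: int, b: int, S: Iterable[int] = ()) -> float:
    """Empirical conditional mutual information I(a; b | S) in nats.

    Always >= 0; ``S`` empty gives the marginal mutual information.
    """
    S = tuple(sorted(set(S)))
    if a == b or a in S or b in S:
        raise ValueError("a, b must be distinct and disjoint from S")
    x = m.values
    n = m.n_rows
    ka = x[:, a - 1].astype(np.int64)
    kb = x[:, b - 1].astype(np.int64)
    ks = _keys(x, S)
    _, sinv = np.unique(ks, return_inverse=True)
    sinv = sinv.astype(np.int64)
    joint = sinv * 9 + ka * 3 + kb
    uj, n_abS = np.unique(joint, return_counts=True)
    sidx = uj // 9
    va = (uj % 9) // 3
    vb = uj % 3
    n_levels = int(sinv.max()) + 1
    n_S = np.bincount(sinv, minlength=n_levels)
    n_aS = np.bincount(sidx * 3 + va, weights=n_abS, minlength=n_levels * 3)
    n_bS = np.bincount(sidx * 3 + vb, weights=n_abS, minlength=n_levels * 3)
    terms = n_abS * (
        np.log(n_abS)
        + np.log(n_S[sidx])
        - np.log(n_aS[sidx * 3 + va])
        - np.log(n_bS[sidx * 3 + vb])
    )
    return max(float(terms.sum()) / n, 0.0)


def delta_score(
    m: MarkerMatrix,
    f: CliqueForest | None,
    a: int,
    b: int,
    S: Iterable[int],
    alpha: float,
    direction: str = "add",
    mode: str = NOMINAL,
) -> ScoreDelta:
    """Score change of a single-edge move with separator S.

    add:    d_deviance = -2 N I(a;b|S), d_dim = +(r_a-1)(r_b-1) prod r_s.
    remove: both signs flipped.
    """
    if direction not in ("add", "remove"):
        raise ValueError(f"unknown direction {direction!r}")
    S = frozenset(S)
    ihat = cmi(m, a, b, S)
    if mode == NOMINAL:
        r = m.levels
        ddim = (int(r[a - 1]) - 1) * (int(r[b - 1]) - 1)
        for s in S:
            ddim *= int(r[s - 1])
    elif mode == OBSERVED:
        cols = sorted(S)
        ddim = (
            _n_observed(m.values, sorted({a, b} | S))
            - _n_observed(m.values, sorted({a} | S))
            - _n_observed(m.values, sorted({b} | S))
            + _n_observed(m.values, cols)
        )
    else:
        raise ValueError(f"unknown dimension mode {mode!r}")
    ddev = -2.0 * m.n_rows * ihat
    if direction == "remove":
        ddev, ddim = -ddev, -ddim
    return ScoreDelta(ddev, int(ddim), alpha, S)


def model_score(
    m: MarkerMatrix,
    f: CliqueForest,
    alpha: float,
    mode: str = NOMINAL,
) -> ModelScore:
    """Convenience: loglik + dimension + IC for one model."""
    ll = decomposable_loglik(m, f)
    dim = model_dimension(f, m.levels, mode=mode, m=m if mode == OBSERVED else None)
    return ModelScore(ll, dim, alpha)
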