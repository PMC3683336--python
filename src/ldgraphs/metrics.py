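"""Complexity and diversity summaries.

Interval heights/widths of a fitted graph, sliding-window haplotype
entropy (natural log), Figure-style median-entropy-by-complexity tables,
sample trees (prefix tries of observed haplotypes), and a pairwise-LD
convenience matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import HAPLOTYPE, MarkerMatrix
from .graphcore import ChromGraph
from .scoring import _keys


@dataclass
class IntervalProfile:
    """For each interval i between SNPs i and i+1: the number of edges
    (j,k) with j <= i < k (height) and their maximum span k-j (width)."""

    heights: list[int]
    widths: list[int]


@dataclass
class EntropyProfile:
    window: int
    window_starts: list[int]
    values: list[float]


@dataclass
class SampleTree:
    """Prefix trie of the observed rows of an interval.

    Nodes are tuples of codes (the root is the empty tuple); ``counts``
    maps each node to the number of rows with that prefix; ``edges`` are
    (parent, child, allele code, count), children ordered by code.
    """

    interval: tuple[int, int]
    counts: dict[tuple[int, ...], int]
    edges: list[tuple[tuple[int, ...], tuple[int, ...], int, int]]


@dataclass
class PairwiseLD:
    r2: np.ndarray
    monomorphic: list[bool]


def heights_widths(g: ChromGraph) -> IntervalProfile:
    h = [0] * max(g.p - 1, 0)
    w = [0] * max(g.p - 1, 0)
    for j, k in g.edges:
        span = k - j
        for i in range(j, k):  # intervals j..k-1 (1-based interval index i)
            h[i - 1] += 1
            if span > w[i - 1]:
                w[i - 1] = span
    return IntervalProfile(h, w)


def window_entropy(m: MarkerMatrix, window: int = 7) -> EntropyProfile:
    """Entropy H = -sum f ln f of the distinct rows in each window of
    ``window`` adjacent SNPs.  Intended for phased haplotype data; genotype
    input is allowed (rows are then multilocus genotypes)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > m.p:
        raise ValueError(f"window {window} exceeds column count {m.p}")
    starts = list(range(1, m.p - window + 2))
    values = []
    for i in starts:
        keys = _keys(m.values, range(i, i + window))
        _, counts = np.unique(keys, return_counts=True)
        f = counts / m.n_rows
        values.append(float(-(f * np.log(f)).sum()))
    return EntropyProfile(window, starts, values)


def entropy_by_complexity(ep: EntropyProfile, ip: IntervalProfile) -> pd.DataFrame:
    """Median window entropy grouped by interval height and by width.

    A window starting at SNP i covers intervals i..i+window-2 and is
    assigned to its central interval (ties resolved to the left).
    """
    rows = []
    w = ep.window
    for start, H in zip(ep.window_starts, ep.values):
        centre = start + (w - 2) // 2 if w >= 2 else start
        centre = min(centre, len(ip.heights))
        rows.append((ip.heights[centre - 1], ip.widths[centre - 1], H))
    if not rows:
        return pd.DataFrame(columns=["group_by", "value", "median_entropy", "n_windows"])
    df = pd.DataFrame(rows, columns=["height", "width", "H"])
    out = []
    for key in ("height", "width"):
        grp = df.groupby(key)["H"]
        for val, med in grp.median().items():
            out.append((key, int(val), float(med), int(grp.count()[val])))
    return pd.DataFrame(out, columns=["group_by", "value", "median_entropy", "n_windows"])


def sample_tree(m: MarkerMatrix, interval: tuple[int, int]) -> SampleTree:
    lo, hi = interval
    if not (1 <= lo <= hi <= m.p):
        raise ValueError(f"bad interval ({lo},{hi}) for p={m.p}")
    sub = m.values[:, lo - 1 : hi]
    counts: dict[tuple[int, ...], int] = {(): m.n_rows}
    for row in sub:
        t = tuple(int(x) for x in row)
        for k in range(1, len(t) + 1):
            pre = t[:k]
            counts[pre] = counts.get(pre, 0) + 1
    edges = []
    for node in sorted(counts):
        if node == ():
            continue
        edges.append((node[:-1], node, node[-1], counts[node]))
    return SampleTree((lo, hi), counts, edges)


def sample_tree_dot(tree: SampleTree) -> str:
    """DOT rendering: root on the left, edge widths proportional to counts,
    edges coloured by allele."""
    total = tree.counts[()]
    colours = {0: "blue", 1: "red", 2: "darkgreen"}
    lines = ["digraph sampletree {", "  rankdir=LR;", '  node [shape=point];']
    name = lambda n: '"%s"' % ("root" if n == () else ".".join(map(str, n)))
    for parent, child, code, count in tree.edges:
        width = max(0.2, 6.0 * count / total)
        lines.append(
            f"  {name(parent)} -> {name(child)} "
            f'[penwidth={width:.2f}, color={colours.get(code, "black")}, '
            f'label="{count}"];'
        )
    lines.append("}")
    return "\n".join(lines)


def pairwise_ld(m: MarkerMatrix, interval: tuple[int, int] | None = None) -> PairwiseLD:
    """Squared correlation of marker codes: haplotype r^2 for phased data,
    composite r^2 (codes 0/1/2) for genotypes.  Monomorphic columns give 0
    and are flagged."""
    if interval is None:
        interval = (1, m.p)
    lo, hi = interval
    if not (1 <= lo <= hi <= m.p):
        raise ValueError(f"bad interval ({lo},{hi}) for p={m.p}")
    sub = m.values[:, lo - 1 : hi].astype(float)
    q = sub.shape[1]
    sd = sub.std(axis=0)
    mono = [s == 0 for s in sd]
    r2 = np.zeros((q, q))
    ok = sd > 0
    if ok.any():
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(sub[:, ok], rowvar=False)
        cc = np.atleast_2d(cc)
        idx = np.flatnonzero(ok)
        r2[np.ix_(idx, idx)] = np.clip(cc**2, 0.0, 1.0)
    return PairwiseLD(r2, mono)


def interval_profile_frame(ip: IntervalProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interval": range(1, len(ip.heights) + 1),
            "height": ip.heights,
            "width": ip.widths,
        }
    )


def entropy_profile_frame(ep: EntropyProfile) -> pd.DataFrame:
    return pd.DataFrame({"start": ep.window_starts, "entropy": ep.values})
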