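"""Reading and validating SNP matrices; graph round-tripping.

Matrices are complete (no missing values): unphased genotypes coded 0/1/2
(ALT-allele counts) or phased haplotypes coded 0/1.  Columns are SNPs in
physical order; vertex/SNP indices are 1-based everywhere, and the on-disk
edge-list format stores 1-based pairs ``i < j``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np

from .graphcore import ChromGraph

GENOTYPE = "genotype"
HAPLOTYPE = "haplotype"

_MAX_CODE = {GENOTYPE: 2, HAPLOTYPE: 1}


class DataError(ValueError):
    """Invalid or unusable input data."""


@dataclass(eq=False)
class MarkerMatrix:
    """N x p matrix of small integer marker codes with metadata."""

    values: np.ndarray
    kind: str
    marker_ids: list[str] | None = None
    positions: list[int] | None = None

    def __post_init__(self):
        if self.kind not in (GENOTYPE, HAPLOTYPE):
            raise DataError(f"unknown kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise DataError("marker codes must be integers")
        if self.marker_ids is None:
            self.marker_ids = [f"snp{j}" for j in range(1, self.p + 1)]
        if len(self.marker_ids) != self.p:
            raise DataError("marker_ids length must equal column count")
        if self.positions is not None:
            if len(self.positions) != self.p:
                raise DataError("positions length must equal column count")
            pos = list(self.positions)
            if any(q < 0 for q in pos):
                raise DataError("positions must be nonnegative")
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise DataError("columns must be in nondecreasing position order")

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    @property
    def p(self) -> int:
        return int(self.values.shape[1])

    @cached_property
    def levels(self) -> np.ndarray:
        """Number of distinct observed codes per column."""
        return np.array(
            [len(np.unique(self.values[:, j])) for j in range(self.p)]
        )

    def select(self, cols: list[int]) -> "MarkerMatrix":
        """Sub-matrix over 1-based column indices, preserving order."""
        idx = [c - 1 for c in cols]
        return MarkerMatrix(
            self.values[:, idx],
            self.kind,
            [self.marker_ids[i] for i in idx],
            [self.positions[i] for i in idx] if self.positions else None,
        )


@dataclass
class ValidationReport:
    n_monomorphic: int = 0
    missing_count: int = 0
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.missing_count == 0 and not self.errors


def validate(m: MarkerMatrix) -> ValidationReport:
    """Report-only check: monomorphic columns, missing codes, range errors.

    Negative codes are treated as missing; downstream use requires
    ``missing_count == 0`` (imputation is delegated to external tools).
    """
    rep = ValidationReport()
    rep.missing_count = int((m.values < 0).sum())
    hi = _MAX_CODE[m.kind]
    for j in range(m.p):
        col = m.values[:, j]
        distinct = np.unique(col[col >= 0])
        if len(distinct) <= 1:
            rep.n_monomorphic += 1
        over = distinct[distinct > hi]
        if len(over):
            rep.errors.append(
                f"column {j + 1} ({m.marker_ids[j]}): codes {over.tolist()} "
                f"out of range for kind {m.kind}"
            )
    return rep


# ---------------------------------------------------------------------------
# Readers


def read_vcf(path: str, mode: str = GENOTYPE) -> MarkerMatrix:
    """Read biallelic SNPs from a VCF.

    genotype mode: one row per sample, code = ALT-allele count.
    haplotype mode: two rows per sample (phased GT required), code = ALT
    indicator; rows 2t-1, 2t hold the two haplotypes of sample t.
    """
    from cyvcf2 import VCF

    if mode not in (GENOTYPE, HAPLOTYPE):
        raise DataError(f"unknown mode {mode!r}")
    vcf = VCF(path)
    samples = list(vcf.samples)
    ids: list[str] = []
    positions: list[int] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        label = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise DataError(f"multiallelic record at {label}")
        gts = var.genotypes
        col = np.empty(len(samples) * (2 if mode == HAPLOTYPE else 1), dtype=np.int8)
        for s, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[2]
            if a0 < 0 or a1 < 0:
                raise DataError(
                    f"missing genotype call for sample {samples[s]} at {label}"
                )
            if mode == HAPLOTYPE:
                if not phased:
                    raise DataError(
                        f"unphased genotype for sample {samples[s]} at {label}; "
                        "haplotype mode requires phased GT"
                    )
                col[2 * s] = a0
                col[2 * s + 1] = a1
            else:
                col[s] = a0 + a1
        cols.append(col)
        ids.append(var.ID if var.ID not in (None, ".") else label)
        positions.append(var.POS)
    if not cols:
        raise DataError(f"no variant records in {path}")
    values = np.column_stack(cols)
    return MarkerMatrix(values, mode, ids, positions)


def read_table(path: str, kind: str = GENOTYPE) -> MarkerMatrix:
    """Read a delimited table: one row per observation, one column per SNP.

    An optional single header line provides marker ids; detected when the
    first line contains any non-integer token.  Delimiter is tab, comma or
    whitespace.
    """
    if kind not in (GENOTYPE, HAPLOTYPE):
        raise DataError(f"unknown kind {kind!r}")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise DataError(f"empty table {path}")

    def split(line: str) -> list[str]:
        if "\t" in line:
            return line.split("\t")
        if "," in line:
            return line.split(",")
        return line.split()

    first = split(lines[0])

    def is_int(tok: str) -> bool:
        try:
            int(tok)
            return True
        except ValueError:
            return False

    header = not all(is_int(t) for t in first)
    ids = first if header else None
    rows = []
    for nr, line in enumerate(lines[1 if header else 0 :], start=1):
        toks = split(line)
        row = []
        for nc, tok in enumerate(toks, start=1):
            if not is_int(tok):
                raise DataError(f"non-integer cell {tok!r} at row {nr}, column {nc}")
            row.append(int(tok))
        rows.append(row)
    if len({len(r) for r in rows}) != 1:
        raise DataError("ragged table: rows have differing column counts")
    values = np.array(rows, dtype=np.int8)
    hi = _MAX_CODE[kind]
    if values.min() < 0 or values.max() > hi:
        bad = int(values.max() if values.max() > hi else values.min())
        raise DataError(f"code {bad} out of range 0..{hi} for kind {kind}")
    m = MarkerMatrix(values, kind, ids)
    return m


# ---------------------------------------------------------------------------
# Graph round-trip

GRAPHML = "graphml"
EDGELIST = "edgelist"


def write_graph(g: ChromGraph, path: str, format: str | None = None) -> None:
    """Write a graph as GraphML (preserves isolated vertices) or a TSV
    edge list of 1-based pairs ``i < j`` (one line per edge)."""
    if format is None:
        format = GRAPHML if str(path).endswith(".graphml") else EDGELIST
    if format == EDGELIST:
        with open(path, "w") as fh:
            for a, b in sorted(g.edges):
                fh.write(f"{a}\t{b}\n")
    elif format == GRAPHML:
        G = nx.Graph()
        G.add_nodes_from(range(1, g.p + 1))
        G.add_edges_from(g.edges)
        G.graph["p"] = g.p
        nx.write_graphml(G, path)
    else:
        raise DataError(f"unknown graph format {format!r}")


def read_graph(path: str, p: int | None = None) -> ChromGraph:
    """Read a graph written by :func:`write_graph`.

    Format is inferred from the ``.graphml`` extension.  For edge lists the
    vertex count is the largest endpoint unless ``p`` is given.
    """
    if str(path).endswith(".graphml"):
        G = nx.read_graphml(path)
        nodes = [int(v) for v in G.nodes]
        pp = int(G.graph.get("p", max(nodes) if nodes else 0))
        edges = [(int(a), int(b)) for a, b in G.edges]
        return ChromGraph(pp, edges)
    edges = []
    with open(path) as fh:
        for nr, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 2:
                raise DataError(f"{path}:{nr}: expected two fields")
            try:
                a, b = int(toks[0]), int(toks[1])
            except ValueError as exc:
                raise DataError(f"{path}:{nr}: non-integer endpoint") from exc
            if a < 1 or b < 1:
                raise DataError(
                    f"{path}:{nr}: vertices are 1-based, got ({a},{b})"
                )
            if a >= b:
                raise DataError(f"{path}:{nr}: require i < j, got ({a},{b})")
            edges.append((a, b))
    if p is None:
        p = max((b for _, b in edges), default=0)
    return ChromGraph(p, edges)


def sha256_of(path: str) -> str:
    """Hex digest of a file, for run manifests."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
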