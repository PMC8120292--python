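"""Containers and I/O for mixed causal graphs over genotype and phenotype nodes.

Adjacency convention: ``A[i, j] = 1`` encodes a directed edge i -> j (rows are
parent nodes, columns are child nodes).  ``A[i, j] = A[j, i] = 1`` encodes an
undirected edge, which in this representation is equivalent to a bidirected
one.  Node *kinds* distinguish genetic variants (instrumental variables) from
phenotypes such as gene expression; the distinction drives the
Mendelian-randomization orientation constraint downstream.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

GENOTYPE = "genotype"
PHENOTYPE = "phenotype"
_KINDS = (GENOTYPE, PHENOTYPE)

# edge states for an unordered node pair
NO_EDGE = "none"
DIRECTED = "->"        # first label -> second label
UNDIRECTED = "--"


class GraphError(ValueError):
    """Raised for malformed graphs or serialization problems."""


@dataclasses.dataclass
class CausalGraph:
    """A labeled mixed graph: node labels, node kinds, binary adjacency matrix.

    Parameters
    ----------
    labels : node names, one per column of ``amat``.
    kinds : per-node tag, each ``"genotype"`` or ``"phenotype"``.
    amat : square 0/1 matrix, ``amat[i, j] = 1`` meaning an edge i -> j.
    """

    labels: tuple[str, ...]
    kinds: tuple[str, ...]
    amat: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        self.kinds = tuple(self.kinds)
        self.amat = np.asarray(self.amat, dtype=np.int8)
        p = len(self.labels)
        if len(set(self.labels)) != p:
            raise GraphError("duplicate node labels")
        if len(self.kinds) != p:
            raise GraphError("kinds length does not match labels")
        for k in self.kinds:
            if k not in _KINDS:
                raise GraphError(f"unknown node kind {k!r}")
        if self.amat.shape != (p, p):
            raise GraphError("adjacency matrix shape does not match labels")
        if not np.isin(self.amat, (0, 1)).all():
            raise GraphError("adjacency entries must be 0 or 1")
        if np.diag(self.amat).any():
            raise GraphError("adjacency diagonal must be zero")

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise GraphError(f"unknown node label {label!r}") from None

    def edge_state(self, a: str, b: str) -> str:
        """Edge state between two labels: 'none', '->', '<-' or '--'."""
        i, j = self.index(a), self.index(b)
        fwd, back = self.amat[i, j], self.amat[j, i]
        if fwd and back:
            return UNDIRECTED
        if fwd:
            return "->"
        if back:
            return "<-"
        return NO_EDGE

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield edges as (a, b, state) with state '->' (a -> b) or '--' (a < b)."""
        p = self.n_nodes
        for i in range(p):
            for j in range(i + 1, p):
                fwd, back = self.amat[i, j], self.amat[j, i]
                if fwd and back:
                    yield self.labels[i], self.labels[j], UNDIRECTED
                elif fwd:
                    yield self.labels[i], self.labels[j], DIRECTED
                elif back:
                    yield self.labels[j], self.labels[i], DIRECTED

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def adjacent(self, a: str, b: str) -> bool:
        return self.edge_state(a, b) != NO_EDGE

    # -- transforms -------------------------------------------------------

    def copy(self) -> "CausalGraph":
        return CausalGraph(self.labels, self.kinds, self.amat.copy())

    def reorder(self, new_labels: Sequence[str]) -> "CausalGraph":
        """Return the same graph with nodes stored in ``new_labels`` order."""
        if sorted(new_labels) != sorted(self.labels):
            raise GraphError("reorder requires the same label set")
        idx = [self.index(l) for l in new_labels]
        return CausalGraph(
            tuple(new_labels),
            tuple(self.kinds[i] for i in idx),
            self.amat[np.ix_(idx, idx)].copy(),
        )

    def canonical(self) -> "CausalGraph":
        """Nodes reordered lexicographically by label."""
        return self.reorder(sorted(self.labels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.kinds == other.kinds
            and np.array_equal(self.amat, other.amat)
        )


def empty_graph(labels: Sequence[str], kinds: Sequence[str]) -> CausalGraph:
    p = len(labels)
    return CausalGraph(tuple(labels), tuple(kinds), np.zeros((p, p), dtype=np.int8))


def graph_from_edges(
    labels: Sequence[str],
    kinds: Sequence[str],
    edges: Iterable[tuple[str, str, str]],
) -> CausalGraph:
    """Build a graph from (a, b, state) tuples; state '->' means a -> b."""
    g = empty_graph(labels, kinds)
    for a, b, state in edges:
        i, j = g.index(a), g.index(b)
        if state == DIRECTED:
            g.amat[i, j] = 1
        elif state == UNDIRECTED:
            g.amat[i, j] = g.amat[j, i] = 1
        else:
            raise GraphError(f"unknown edge state {state!r}")
    return g


def canonical_form(g: CausalGraph) -> str:
    """Permutation-invariant string key for a labeled mixed graph.

    Two graphs with identical labeled edge sets and orientation states map to
    the same key regardless of node storage order; any difference in labels,
    kinds, or edges yields a different key.
    """
    cg = g.canonical()
    nodes = ";".join(f"{l}:{k}" for l, k in zip(cg.labels, cg.kinds))
    parts = []
    for a, b, state in cg.edges():
        if state == UNDIRECTED:
            x, y = sorted((a, b))
            parts.append(f"{x}--{y}")
        else:
            parts.append(f"{a}->{b}")
    return nodes + "|" + ",".join(sorted(parts))


# -- data matrix input ----------------------------------------------------


def read_data_matrix(
    path, n_genotype_columns: int, sep: str | None = None
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...]]:
    """Read a samples x variables delimited text file with a header row.

    The first ``n_genotype_columns`` columns are genotype (instrumental
    variable) nodes; the remainder are phenotypes.  Returns the numeric data
    frame, the column labels, and the per-column kinds.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[0] == 0:
        raise GraphError(f"{path}: no data rows below the header")
    if len(set(df.columns)) != df.shape[1]:
        raise GraphError(f"{path}: duplicate column labels")
    if not 0 <= n_genotype_columns <= df.shape[1]:
        raise GraphError(
            f"n_genotype_columns={n_genotype_columns} out of range for "
            f"{df.shape[1]} columns"
        )
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise GraphError(
                f"{path}: non-numeric value in column {col!r}, data row {row}"
            )
        df[col] = vals.astype(float)
    labels = tuple(str(c) for c in df.columns)
    kinds = tuple(
        GENOTYPE if i < n_genotype_columns else PHENOTYPE for i in range(len(labels))
    )
    return df, labels, kinds


# -- graph serialization ---------------------------------------------------

_KINDS_PREFIX = "#kinds:"


def write_graph(g: CausalGraph, path, fmt: str = "adjacency-tsv") -> None:
    """Write a graph as a labeled adjacency TSV or a Graphviz DOT file.

    The TSV dialect is a square 0/1 matrix (rows = parents, columns =
    children) preceded by a ``#kinds:`` comment line so that node kinds
    round-trip.  DOT renders directed edges as arrows, undirected pairs as a
    single edge with ``dir=none``, genotype nodes as triangles and phenotype
    nodes as circles.
    """
    if fmt == "adjacency-tsv":
        with open(path, "w") as fh:
            fh.write(_KINDS_PREFIX + " " + " ".join(g.kinds) + "\n")
            fh.write("\t" + "\t".join(g.labels) + "\n")
            for i, lab in enumerate(g.labels):
                fh.write(lab + "\t" + "\t".join(str(int(v)) for v in g.amat[i]) + "\n")
    elif fmt == "dot":
        lines = ["digraph G {"]
        for lab, kind in zip(g.labels, g.kinds):
            shape = "triangle" if kind == GENOTYPE else "ellipse"
            lines.append(f'  "{lab}" [shape={shape}];')
        for a, b, state in g.edges():
            if state == UNDIRECTED:
                lines.append(f'  "{a}" -> "{b}" [dir=none];')
            else:
                lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise GraphError(f"unknown graph format {fmt!r}")


def read_graph(path) -> CausalGraph:
    """Read a graph written in the adjacency-TSV dialect of :func:`write_graph`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    kinds: tuple[str, ...] | None = None
    if lines and lines[0].startswith(_KINDS_PREFIX):
        kinds = tuple(lines[0][len(_KINDS_PREFIX):].split())
        lines = lines[1:]
    if not lines:
        raise GraphError(f"{path}: empty graph file")
    labels = tuple(lines[0].split("\t")[1:])
    p = len(labels)
    amat = np.zeros((p, p), dtype=np.int8)
    if len(lines) != p + 1:
        raise GraphError(f"{path}: expected {p} matrix rows, got {len(lines) - 1}")
    for i, ln in enumerate(lines[1:]):
        cells = ln.split("\t")
        if cells[0] != labels[i]:
            raise GraphError(f"{path}: row label {cells[0]!r} != column label")
        if len(cells) != p + 1:
            raise GraphError(f"{path}: ragged row {i}")
        amat[i] = [int(c) for c in cells[1:]]
    if kinds is None:
        kinds = (PHENOTYPE,) * p
    return CausalGraph(labels, kinds, amat)
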