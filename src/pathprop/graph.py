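"""Gene interaction network: loading, validation, symmetric normalization.

The network is an undirected, unweighted graph over gene symbols. The
propagation operator is the degree-normalized adjacency
``D^{-1/2} G D^{-1/2}``; rows and columns of isolated nodes are zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ParseError

log = logging.getLogger(__name__)

#: tokens that mark the first line of an edge list as a header
_HEADER_TOKENS = {
    "gene", "gene1", "gene2", "genea", "geneb", "source", "target",
    "node1", "node2", "from", "to", "symbol", "symbol1", "symbol2",
    "interactor_a", "interactor_b", "protein1", "protein2",
}


def normalize_symbol(symbol: str) -> str:
    """Canonical gene symbol: whitespace-stripped, uppercased."""
    return symbol.strip().upper()


@dataclass
class GeneNetwork:
    """Undirected gene graph with a symmetric binary adjacency matrix.

    Nodes are ordered lexicographically so all derived matrices and
    outputs are reproducible for a given input.
    """

    nodes: tuple[str, ...]
    adjacency: sp.csr_matrix
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def degrees(self) -> np.ndarray:
        """Integer node degrees (row sums of the adjacency)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def neighbors(self, gene: str) -> list[str]:
        i = self.index[gene]
        row = self.adjacency.getrow(i)
        return [self.nodes[j] for j in row.indices]

    def edge_set(self) -> set[frozenset[str]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return {
            frozenset((self.nodes[i], self.nodes[j]))
            for i, j in zip(coo.row, coo.col)
        }

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "GeneNetwork":
        """Build a network from symbol pairs.

        Self-loops are dropped; duplicate and reversed-duplicate edges
        collapse to a single undirected edge. ``extra_nodes`` lets callers
        retain isolated nodes.
        """
        clean: set[frozenset[str]] = set()
        node_set: set[str] = {normalize_symbol(g) for g in extra_nodes}
        n_self = 0
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if not a or not b:
                raise ValueError("empty gene symbol in edge")
            if a == b:
                n_self += 1
                node_set.add(a)
                continue
            clean.add(frozenset((a, b)))
            node_set.update((a, b))
        if n_self:
            log.warning("dropped %d self-loop edge(s)", n_self)
        nodes = tuple(sorted(node_set))
        idx = {g: i for i, g in enumerate(nodes)}
        rows, cols = [], []
        for pair in clean:
            a, b = tuple(pair)
            i, j = idx[a], idx[b]
            rows.extend((i, j))
            cols.extend((j, i))
        data = np.ones(len(rows), dtype=np.float64)
        adj = sp.csr_matrix(
            (data, (rows, cols)), shape=(len(nodes), len(nodes))
        )
        return cls(nodes=nodes, adjacency=adj)


@dataclass
class NormalizedAdjacency:
    """Symmetric degree-normalized adjacency ``D^{-1/2} G D^{-1/2}``."""

    matrix: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def load_edge_list(
    path: str | Path,
    fmt: str = "tsv-pairs",
    node_file: str | Path | None = None,
) -> GeneNetwork:
    """Read an edge list (``tsv-pairs`` or ``sif``) into a :class:`GeneNetwork`.

    tsv-pairs lines carry two symbols (a third, weight-like column is
    ignored with a warning: interactions are treated as binary). SIF lines
    carry ``node relation target [target ...]``; the relation is ignored.
    A header line is skipped when its tokens match common column names.
    Isolated nodes survive only if listed in ``node_file``.
    """
    if fmt not in ("tsv-pairs", "sif"):
        raise ValueError(f"unknown edge list format: {fmt!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    edges: list[tuple[str, str]] = []
    warned_weights = False
    first_data = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if first_data:
            first_data = False
            if any(f.strip().lower() in _HEADER_TOKENS for f in fields):
                continue
        if fmt == "tsv-pairs":
            if len(fields) == 3 and not warned_weights:
                log.warning(
                    "%s:%d: third column ignored (edges are unweighted)",
                    path.name, lineno,
                )
                warned_weights = True
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
        else:  # sif
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: SIF line needs >=3 fields, got {len(fields)}"
                )
            for target in fields[2:]:
                edges.append((fields[0], target))
    extra: list[str] = []
    if node_file is not None:
        extra = [
            ln.strip() for ln in Path(node_file).read_text().splitlines()
            if ln.strip()
        ]
    if not edges and not extra:
        raise ParseError(f"{path}: no edges found and no node file given")
    return GeneNetwork.from_edges(edges, extra_nodes=extra)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write the canonical (lexicographically sorted) edge list."""
    pairs = sorted(tuple(sorted(e)) for e in net.edge_set())
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def write_node_manifest(net: GeneNetwork, path: str | Path) -> None:
    """Write the node-order manifest TSV: index, symbol, degree."""
    deg = net.degrees
    with open(path, "w") as fh:
        fh.write("index\tsymbol\tdegree\n")
        for i, g in enumerate(net.nodes):
            fh.write(f"{i}\t{g}\t{deg[i]}\n")


def normalized_adjacency(net: GeneNetwork) -> NormalizedAdjacency:
    """Construct ``D^{-1/2} G D^{-1/2}`` with zeros for degree-0 nodes."""
    d = net.degrees.astype(np.float64)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    dinv = sp.diags(inv_sqrt)
    mat = (dinv @ net.adjacency @ dinv).tocsr()
    return NormalizedAdjacency(matrix=mat)
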