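"""Protein interaction network (PIN) ingestion and validation.

Signalling entropy is the entropy rate of an expression-weighted random walk
on an undirected gene graph.  For the walk's stationary distribution to exist
and be unique, the chain must be irreducible and aperiodic, which for this
construction is equivalent to the graph being connected and non-bipartite.
This module reads edge lists, restricts them to the measured genes, extracts
the largest connected component and enforces those Perron–Frobenius
preconditions before anything downstream runs.

Gene identifiers are matched exactly (case-sensitive) and node order is the
lexicographic sort of the labels, so every downstream matrix is reproducible
bit-for-bit from the same inputs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import BipartiteNetworkError, DegenerateNetworkError, ParseError

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

# Tokens that mark a first row as a header rather than a gene pair.
_HEADER_TOKENS = {
    "gene1", "gene2", "gene_a", "gene_b", "genea", "geneb",
    "source", "target", "from", "to", "node1", "node2",
    "protein1", "protein2", "interactor_a", "interactor_b",
    "interactora", "interactorb", "symbol1", "symbol2",
}


@dataclass(frozen=True, eq=False)
class InteractomeGraph:
    """A validated, connected, non-bipartite undirected gene graph.

    Attributes
    ----------
    nodes
        Gene identifiers in lexicographic order; this order defines the row
        and column order of every matrix built on the graph.
    adjacency
        Symmetric 0/1 CSR matrix aligned to ``nodes``.
    """

    nodes: tuple[str, ...]
    adjacency: sp.csr_matrix = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except AttributeError:
            object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.nodes)})
            return self._index[gene]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_scipy_sparse_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.nodes)))

    def edge_list(self) -> list[Edge]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(coo.row, coo.col)]

    def summary(self) -> dict:
        """JSON-serialisable validation summary."""
        deg = self.degrees
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "min_degree": int(deg.min()),
            "mean_degree": float(deg.mean()),
            "bipartite": False,
        }


def read_edge_list(path: str | Path, dialect: str = "tsv2col") -> set[Edge]:
    """Read an undirected edge list from a two-column TSV or a SIF file.

    Self-loops are dropped and duplicate (unordered) edges collapsed; the
    counts of both are reported through the module logger.  For the ``sif``
    dialect the interaction-type column is ignored and rows may list several
    targets (``A pp B C`` yields A–B and A–C).

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"tsv2col"`` (two tab/whitespace-separated identifier columns, an
        optional header row auto-detected from common header tokens) or
        ``"sif"``.

    Raises
    ------
    ParseError
        On a row with the wrong number of columns, naming the line number.
    """
    path = Path(path)
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")

    edges: set[Edge] = set()
    n_dup = 0
    n_self = 0
    first_data_row = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if dialect == "tsv2col":
                if len(tokens) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 columns, found {len(tokens)}"
                    )
                if first_data_row and all(t.lower() in _HEADER_TOKENS for t in tokens):
                    first_data_row = False
                    continue
                pairs = [(tokens[0], tokens[1])]
            else:  # sif
                if len(tokens) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF row needs >= 3 columns, found {len(tokens)}"
                    )
                pairs = [(tokens[0], t) for t in tokens[2:]]
            first_data_row = False
            for a, b in pairs:
                if a == b:
                    n_self += 1
                    continue
                edge = (a, b) if a < b else (b, a)
                if edge in edges:
                    n_dup += 1
                else:
                    edges.add(edge)
    logger.info(
        "read %d edges from %s (%d duplicates dropped, %d self-loops dropped)",
        len(edges), path, n_dup, n_self,
    )
    return edges


def is_bipartite(graph: nx.Graph) -> tuple[bool, object]:
    """Two-colouring test with a witness.

    Returns ``(True, (set_a, set_b))`` with the bipartition on success, or
    ``(False, odd_cycle)`` with an explicit odd cycle (list of nodes) on
    failure.  The input must be connected.
    """
    colour: dict = {}
    parent: dict = {}
    # Deterministic start for reproducible witnesses.
    root = min(graph.nodes)
    colour[root] = 0
    parent[root] = None
    stack = [root]
    while stack:
        u = stack.pop()
        for v in sorted(graph.neighbors(u)):
            if v not in colour:
                colour[v] = 1 - colour[u]
                parent[v] = u
                stack.append(v)
            elif colour[v] == colour[u]:
                # Odd cycle: walk both nodes up to their common ancestor.
                pu = _path_to_root(u, parent)
                pv = _path_to_root(v, parent)
                common = next(x for x in pu if x in set(pv))
                cyc = pu[: pu.index(common) + 1] + pv[: pv.index(common)][::-1]
                return False, cyc
    part_a = {n for n, c in colour.items() if c == 0}
    part_b = set(colour) - part_a
    return True, (part_a, part_b)


def _path_to_root(node, parent) -> list:
    path = [node]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def restrict_and_validate(
    edges: Iterable[Edge], measured_genes: Iterable[str] | None = None
) -> InteractomeGraph:
    """Restrict a raw edge set to the measured genes and validate it.

    Drops nodes without a measurement, keeps the largest connected component
    (ties broken in favour of the component containing the lexicographically
    smallest label) and checks non-bipartiteness.  Idempotent: running it on
    a validated graph's own edge list returns the identical graph.

    Raises
    ------
    DegenerateNetworkError
        If fewer than 3 nodes survive.
    BipartiteNetworkError
        If the surviving component is bipartite (the error carries the
        two-colouring witness).
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        raise DegenerateNetworkError("empty edge set")
    if measured_genes is not None:
        keep = set(measured_genes)
        g.remove_nodes_from([n for n in list(g) if n not in keep])

    components = list(nx.connected_components(g))
    if not components:
        raise DegenerateNetworkError("no nodes remain after restriction")
    max_size = max(len(c) for c in components)
    largest = min(
        (c for c in components if len(c) == max_size), key=lambda c: min(c)
    )
    if len(largest) < 3:
        raise DegenerateNetworkError(
            f"largest usable component has only {len(largest)} node(s); "
            "a random walk needs at least 3"
        )
    sub = g.subgraph(largest)
    bip, witness = is_bipartite(sub)
    if bip:
        raise BipartiteNetworkError(
            "network component is bipartite (random walk would be periodic); "
            f"two-colouring witness: {sorted(witness[0])} | {sorted(witness[1])}",
            partition=witness,
        )

    nodes = tuple(sorted(largest))
    adjacency = nx.to_scipy_sparse_array(sub, nodelist=nodes, format="csr", dtype=np.float64)
    adjacency = sp.csr_matrix(adjacency)
    logger.info("validated network: %d nodes, %d edges", len(nodes), adjacency.nnz // 2)
    return InteractomeGraph(nodes=nodes, adjacency=adjacency)


def from_networkx(g: nx.Graph) -> InteractomeGraph:
    """Validate an existing networkx graph (convenience wrapper)."""
    return restrict_and_validate((tuple(e) for e in g.edges()), None)
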