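"""Directed-graph data model, plain-text edge-list I/O and structural queries.

The :class:`DirectedGraph` is the substrate of the whole package: an immutable
simple directed graph over nodes ``0 .. N-1`` with a deterministic edge order.
Link weights are deliberately not stored here — structural controllability
depends only on the zero/nonzero pattern of the adjacency matrix, and the
exact-controllability comparison draws its own weights.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

Edge = tuple[int, int]

__all__ = [
    "DirectedGraph",
    "Edge",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "scc_edge_count",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class DirectedGraph:
    """Immutable simple directed graph on nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes
        Number of nodes ``N`` (>= 1).  Isolated nodes are allowed.
    edges
        Ordered tuple of directed ``(source, target)`` pairs.  Self-loops and
        duplicates are rejected; iteration order is the construction order and
        is therefore deterministic.
    labels
        Optional original node identifiers (``labels[i]`` is the external id
        of internal node ``i``); used only for reporting after relabelling an
        input file.  ``None`` means internal and external ids coincide.
    """

    n_nodes: int
    edges: tuple[Edge, ...]
    labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        seen: set[Edge] = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) not allowed")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u},{v}) endpoint outside 0..{self.n_nodes - 1}")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u},{v})")
            seen.add((u, v))
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels length must equal n_nodes")

    # -- basic queries ---------------------------------------------------

    @property
    def N(self) -> int:
        return self.n_nodes

    @property
    def M(self) -> int:
        return len(self.edges)

    @cached_property
    def edge_array(self) -> np.ndarray:
        """``(M, 2)`` int64 array of edges in iteration order."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(self.edges, dtype=np.int64)

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        """Boolean ``N x N`` CSR adjacency (row = source)."""
        ea = self.edge_array
        data = np.ones(len(ea), dtype=np.int8)
        return sp.csr_matrix((data, (ea[:, 0], ea[:, 1])), shape=(self.N, self.N))

    @cached_property
    def _csr_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR-like ``(indptr, neighbours, edge_ids)`` keeping edge indices.

        ``edge_ids[k]`` is the position in :attr:`edges` of the edge from the
        owning row to ``neighbours[k]`` — used by the load kernel to write
        per-edge results in the canonical edge order.
        """
        ea = self.edge_array
        order = np.argsort(ea[:, 0], kind="stable")
        nbrs = ea[order, 1]
        eids = order.astype(np.int64)
        counts = np.bincount(ea[:, 0], minlength=self.N)
        indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        return indptr, nbrs.astype(np.int64), eids

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in set(self.edges) if self.M > 50 else (u, v) in self.edges

    def remove_edges(self, removed: Iterable[Edge]) -> "DirectedGraph":
        """Return a copy without ``removed`` edges (node set unchanged)."""
        removed = set(removed)
        unknown = removed - set(self.edges)
        if unknown:
            raise ValueError(f"edges not in graph: {sorted(unknown)[:5]}")
        return DirectedGraph(
            self.n_nodes,
            tuple(e for e in self.edges if e not in removed),
            self.labels,
        )

    def to_networkx(self):
        """Export as :class:`networkx.DiGraph` (isolated nodes included)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges)
        return g


# -- edge-list I/O -------------------------------------------------------

_NODES_HEADER = re.compile(r"#\s*nodes\s+(\d+)\s*$")


def read_edge_list(path: str | Path) -> DirectedGraph:
    """Read a plain-text edge list: one ``source target`` pair per line.

    Lines starting with ``#`` are comments; an optional ``#nodes N`` header
    declares isolated nodes.  Duplicate lines and self-loops are dropped with
    a logged count.  Arbitrary non-negative integer ids are relabelled to
    consecutive 0-based ids (ascending); the original ids are retained in
    :attr:`DirectedGraph.labels`.
    """
    path = Path(path)
    declared_n: int | None = None
    edges: list[Edge] = []
    seen: set[Edge] = set()
    mentioned: set[int] = set()  # self-loop lines still declare their node
    n_dup = n_self = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _NODES_HEADER.match(line)
                if m:
                    declared_n = int(m.group(1))
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two tokens, got {len(tokens)}"
                )
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: non-integer node id {tokens!r}"
                ) from exc
            if u < 0 or v < 0:
                raise EdgeListParseError(f"{path}:{lineno}: negative node id")
            mentioned.add(u)
            mentioned.add(v)
            if u == v:
                n_self += 1
                continue
            if (u, v) in seen:
                n_dup += 1
                continue
            seen.add((u, v))
            edges.append((u, v))
    if not mentioned and declared_n is None:
        raise EdgeListParseError(f"{path}: empty edge list and no '#nodes N' header")
    if n_dup or n_self:
        logger.info(
            "%s: dropped %d duplicate and %d self-loop line(s)", path, n_dup, n_self
        )
    label_set = set(mentioned)
    if declared_n is not None:
        label_set |= set(range(declared_n))
    labels = sorted(label_set)
    index = {lab: i for i, lab in enumerate(labels)}
    mapped = tuple((index[u], index[v]) for u, v in edges)
    identity = labels == list(range(len(labels)))
    return DirectedGraph(len(labels), mapped, None if identity else tuple(labels))


def write_edge_list(graph: DirectedGraph, path: str | Path) -> None:
    """Write ``graph`` in the edge-list format (internal 0-based ids).

    Always emits a ``#nodes N`` header so isolated nodes round-trip.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#nodes {graph.N}\n")
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")


# -- strongly connected components ---------------------------------------


def scc_edge_count(graph: DirectedGraph, largest_only: bool = False) -> int:
    """Number of edges inside strongly connected components of size >= 2.

    Cascading failures concentrate inside SCCs, so the surviving SCC edge
    count tracks the damage a cascade has done to the cyclic core.  By
    default edges of *all* nontrivial SCCs are summed (stable under the ties
    that appear after heavy cascades); ``largest_only`` restricts the count
    to the SCC with the most nodes (smallest component label on ties).
    """
    if graph.M == 0:
        return 0
    _, comp = connected_components(graph.adjacency, directed=True, connection="strong")
    sizes = np.bincount(comp)
    ea = graph.edge_array
    internal = comp[ea[:, 0]] == comp[ea[:, 1]]
    if not largest_only:
        big = sizes[comp[ea[:, 0]]] >= 2
        return int(np.count_nonzero(internal & big))
    nontrivial = np.flatnonzero(sizes >= 2)
    if len(nontrivial) == 0:
        return 0
    target = nontrivial[np.argmax(sizes[nontrivial])]
    return int(np.count_nonzero(internal & (comp[ea[:, 0]] == target)))
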