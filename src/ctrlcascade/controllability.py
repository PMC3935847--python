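"""Structural controllability of directed networks via maximum matching.

For linear time-invariant dynamics ``dx/dt = A x + B u`` on a directed
network, the minimum number of independent input signals ``N_D`` needed for
full (structural) controllability equals the number of unmatched nodes of a
maximum matching of the network, where a matching is a set of directed edges
no two of which share a source or share a target (equivalently, a bipartite
matching between out-copies and in-copies of the nodes).  Unmatched nodes —
nodes with no inbound matched edge — are the *driver nodes*: attaching one
input to each of them renders the system controllable for almost every
choice of edge weights.  Although many maximum matchings may exist, the
number of unmatched nodes is the same in all of them, so ``N_D`` is well
defined.

Edges play three distinct roles for controllability:

* **critical** — removing the edge increases ``N_D``; equivalently the edge
  belongs to *every* maximum matching;
* **redundant** — the edge belongs to *no* maximum matching, so its removal
  cannot affect the driver set;
* **ordinary** — in some but not all maximum matchings.

An independent check is the exact-controllability count for a concrete
weighted adjacency matrix ``A``: ``N_D = max_lambda (N - rank(lambda I - A))``
over the distinct eigenvalues ``lambda`` of ``A``.  With generic (random
continuous) weights this agrees with the structural count; with identical
weights it may exceed it on structured graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import maximum_bipartite_matching

from .graph_core import DirectedGraph, Edge

__all__ = [
    "Matching",
    "ControllabilityReport",
    "EdgeClassification",
    "CRITICAL",
    "ORDINARY",
    "REDUNDANT",
    "maximum_matching",
    "driver_report",
    "classify_edges",
    "exact_driver_count",
]

CRITICAL = "critical"
ORDINARY = "ordinary"
REDUNDANT = "redundant"

#: dense linear algebra guard for exact_driver_count
_EXACT_MAX_N = 5000
#: eigenvalues closer than this are grouped as one distinct eigenvalue
_EIG_TOL = 1e-8


@dataclass(frozen=True)
class Matching:
    """A set of directed edges, no two sharing a source or a target."""

    matched_edges: frozenset[Edge]

    def __post_init__(self) -> None:
        sources = [u for u, _ in self.matched_edges]
        targets = [v for _, v in self.matched_edges]
        if len(set(sources)) != len(sources) or len(set(targets)) != len(targets):
            raise ValueError("matching edges share an endpoint")

    @property
    def size(self) -> int:
        return len(self.matched_edges)

    @property
    def matched_nodes(self) -> frozenset[int]:
        """Nodes with an inbound matched edge."""
        return frozenset(v for _, v in self.matched_edges)


@dataclass(frozen=True)
class ControllabilityReport:
    """Driver-node summary of one graph."""

    n_nodes: int
    matching: Matching
    n_drivers: int
    driver_nodes: frozenset[int]

    @property
    def n_drivers_density(self) -> float:
        """``n_D = N_D / N``, the size-independent driver density."""
        return self.n_drivers / self.n_nodes


def _matching_pairs(n: int, us: np.ndarray, vs: np.ndarray) -> list[Edge]:
    """Maximum bipartite matching of out-copies vs in-copies, as edge pairs."""
    if len(us) == 0:
        return []
    bi = sp.csr_matrix(
        (np.ones(len(us), dtype=np.int8), (us, vs)), shape=(n, n)
    )
    col_of_row = maximum_bipartite_matching(bi, perm_type="column")
    return [(int(u), int(col_of_row[u])) for u in range(n) if col_of_row[u] != -1]


def _matching_size(n: int, us: np.ndarray, vs: np.ndarray) -> int:
    if len(us) == 0:
        return 0
    bi = sp.csr_matrix(
        (np.ones(len(us), dtype=np.int8), (us, vs)), shape=(n, n)
    )
    col_of_row = maximum_bipartite_matching(bi, perm_type="column")
    return int(np.count_nonzero(col_of_row != -1))


def maximum_matching(graph: DirectedGraph) -> Matching:
    """A maximum-cardinality matching of ``graph``.

    Computed with Hopcroft–Karp on the bipartite representation (directed
    edge ``(i, j)`` becomes bipartite edge ``i+ — j-``).  The returned
    matching is one deterministic representative; only its cardinality is
    invariant across maximum matchings.
    """
    ea = graph.edge_array
    return Matching(frozenset(_matching_pairs(graph.N, ea[:, 0], ea[:, 1])))


def driver_report(graph: DirectedGraph) -> ControllabilityReport:
    """Driver-node count ``N_D = max(N - |M*|, 1)`` and one driver set.

    When the matching is perfect the matched edges decompose into disjoint
    cycles and a single input suffices; by convention the driver is then the
    lowest-id node (which necessarily lies on a matched cycle).
    """
    m = maximum_matching(graph)
    unmatched = frozenset(range(graph.N)) - m.matched_nodes
    if unmatched:
        return ControllabilityReport(graph.N, m, len(unmatched), unmatched)
    return ControllabilityReport(graph.N, m, 1, frozenset({0}))


@dataclass(frozen=True)
class EdgeClassification:
    """Per-edge controllability role labels (partition of the edge set)."""

    categories: dict[Edge, str]

    @cached_property
    def counts(self) -> dict[str, int]:
        c = {CRITICAL: 0, ORDINARY: 0, REDUNDANT: 0}
        for cat in self.categories.values():
            c[cat] += 1
        return c

    @cached_property
    def densities(self) -> dict[str, float]:
        m = len(self.categories)
        return {k: (v / m if m else 0.0) for k, v in self.counts.items()}

    def __getitem__(self, edge: Edge) -> str:
        return self.categories[edge]


def classify_edges(graph: DirectedGraph) -> EdgeClassification:
    """Label every edge critical / ordinary / redundant.

    ``e`` is critical iff the maximum-matching size drops when ``e`` is
    removed (equivalently ``N_D`` rises).  ``e = (u, v)`` lies in *some*
    maximum matching iff ``1 + |M*(G - u+ - v-)| = |M*(G)|`` (force ``e``
    into the matching by deleting its bipartite endpoints); if it lies in
    none it is redundant.  Everything else is ordinary.
    """
    ea = graph.edge_array
    us, vs = ea[:, 0], ea[:, 1]
    base = _matching_size(graph.N, us, vs)
    cats: dict[Edge, str] = {}
    for k, (u, v) in enumerate(graph.edges):
        keep = np.ones(len(us), dtype=bool)
        keep[k] = False
        if _matching_size(graph.N, us[keep], vs[keep]) < base:
            cats[(u, v)] = CRITICAL
            continue
        free = (us != u) & (vs != v)
        in_some = 1 + _matching_size(graph.N, us[free], vs[free]) == base
        cats[(u, v)] = ORDINARY if in_some else REDUNDANT
    return EdgeClassification(cats)


def exact_driver_count(
    graph: DirectedGraph,
    weight_mode: str = "identical",
    seed: int | None = None,
) -> int:
    """Minimum input count from the eigenvalue-multiplicity rank condition.

    Builds a weighted adjacency matrix ``A`` (``identical``: every edge
    weight 1; ``random``: independent uniform draws on ``(0, 1]``) and
    returns ``max_lambda (N - rank(lambda I - A))`` over the distinct
    eigenvalues of ``A``, but at least 1.  Rank uses the standard
    singular-value cutoff ``N * eps * s_max``; eigenvalues within 1e-8 of
    each other are grouped as one.
    """
    if graph.N > _EXACT_MAX_N:
        raise ValueError(f"N={graph.N} exceeds dense-eigenvalue guard {_EXACT_MAX_N}")
    if weight_mode not in ("identical", "random"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    n = graph.N
    a = np.zeros((n, n))
    ea = graph.edge_array
    if len(ea):
        if weight_mode == "identical":
            a[ea[:, 0], ea[:, 1]] = 1.0
        else:
            rng = np.random.default_rng(seed)
            a[ea[:, 0], ea[:, 1]] = 1.0 - rng.random(len(ea))  # uniform on (0, 1]
    eigvals = np.linalg.eigvals(a)
    order = np.lexsort((eigvals.imag, eigvals.real))
    eigvals = eigvals[order]
    # A defective eigenvalue with a size-b Jordan block scatters numerically
    # over a radius ~ eps**(1/b), which no fixed clustering tolerance can
    # absorb; 0 is by far the most common such eigenvalue on sparse digraphs
    # (nilpotent structure), so it is always evaluated explicitly.
    candidates: list[complex] = [0.0]
    cluster: list[complex] = []
    for lam in list(eigvals) + [None]:  # type: ignore[list-item]
        if cluster and (lam is None or abs(lam - cluster[-1]) > _EIG_TOL):
            # geometric multiplicity <= algebraic: singleton clusters cannot
            # beat the floor of 1, so they need no rank computation
            if len(cluster) > 1:
                candidates.append(complex(np.mean(cluster)))
            cluster = []
        if lam is not None:
            cluster.append(lam)
    best = 1
    for rep in candidates:
        mult = n - np.linalg.matrix_rank(rep * np.eye(n) - a)
        best = max(best, int(mult))
    return best
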