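"""Edge loads, capacities and betweenness-driven cascading edge failures.

The load of an edge is the total number of shortest directed paths (over all
ordered node pairs) that traverse it — a raw count, not the fractional
Brandes betweenness: when several equal-length shortest paths exist between
a pair, each full path contributes 1 to every edge it uses.  The fractional
convention is available behind a flag for sensitivity analysis.

Each edge is assigned a fixed capacity ``C_e = (1 + alpha) * L_e(0)``
proportional to its *initial* load, with tolerance parameter ``alpha >= 0``.
After an attack removes edges, shortest paths reroute; every edge whose new
load strictly exceeds its capacity fails, all overloaded edges are removed
simultaneously, loads are recomputed, and the process repeats until no edge
is overloaded.  The per-stage trace records the failed edges, the driver-node
count and the SCC edge count, which is how the co-evolution of
controllability and damage is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
from numba import njit

from .controllability import driver_report
from .graph_core import DirectedGraph, Edge, scc_edge_count

__all__ = [
    "CapacityMap",
    "CascadeStage",
    "CascadeTrace",
    "compute_loads",
    "assign_capacities",
    "run_cascade",
]


@njit(cache=True)
def _loads_kernel(indptr, nbrs, eids, n, m, fractional):  # pragma: no cover
    loads = np.zeros(m)
    dist = np.empty(n, dtype=np.int64)
    sigma = np.zeros(n)
    acc = np.zeros(n)
    order = np.empty(n, dtype=np.int64)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
            sigma[i] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            u = order[head]
            head += 1
            du = dist[u]
            for k in range(indptr[u], indptr[u + 1]):
                v = nbrs[k]
                if dist[v] == -1:
                    dist[v] = du + 1
                    order[tail] = v
                    tail += 1
                if dist[v] == du + 1:
                    sigma[v] += sigma[u]
        # reverse-BFS accumulation over the shortest-path DAG rooted at s:
        # acc[v] = sum over DAG successors w of (1 + acc[w])  (raw counts)
        #        = dependency delta(v) in the fractional convention
        for i in range(tail - 1, -1, -1):
            v = order[i]
            dv = dist[v]
            total = 0.0
            for k in range(indptr[v], indptr[v + 1]):
                w = nbrs[k]
                if dist[w] == dv + 1:
                    if fractional:
                        total += sigma[v] / sigma[w] * (1.0 + acc[w])
                    else:
                        total += 1.0 + acc[w]
            acc[v] = total
        for i in range(tail):
            u = order[i]
            du = dist[u]
            for k in range(indptr[u], indptr[u + 1]):
                v = nbrs[k]
                if dist[v] == du + 1:
                    if fractional:
                        loads[eids[k]] += sigma[u] / sigma[v] * (1.0 + acc[v])
                    else:
                        loads[eids[k]] += sigma[u] * (1.0 + acc[v])
    return loads


def compute_loads(graph: DirectedGraph, fractional: bool = False) -> dict[Edge, float]:
    """Shortest-path load of every edge.

    Raw-count convention (default): ``L_e = sum over ordered reachable pairs
    (s, t) of the number of distinct shortest s->t paths through e``.  With
    ``fractional=True`` each pair contributes ``sigma_st(e) / sigma_st``
    instead (Brandes edge betweenness).
    """
    if graph.M == 0:
        return {}
    indptr, nbrs, eids = graph._csr_arrays
    loads = _loads_kernel(indptr, nbrs, eids, graph.N, graph.M, fractional)
    return {e: float(loads[k]) for k, e in enumerate(graph.edges)}


@dataclass(frozen=True)
class CapacityMap:
    """Fixed per-edge capacities ``C_e = (1 + alpha) * L_e(0)``."""

    alpha: float
    capacities: Mapping[Edge, float]

    def __getitem__(self, edge: Edge) -> float:
        return self.capacities[edge]


def assign_capacities(loads: Mapping[Edge, float], alpha: float) -> CapacityMap:
    """Capacities proportional to the intact graph's loads.

    ``alpha`` is the tolerance: the fractional load headroom every edge has
    before it fails.  Capacities are frozen at trigger time and never updated
    during a cascade.
    """
    if alpha < 0:
        raise ValueError("tolerance alpha must be >= 0")
    return CapacityMap(alpha, {e: (1.0 + alpha) * load for e, load in loads.items()})


@dataclass(frozen=True)
class CascadeStage:
    """State after one synchronous round of overload removals.

    Stage 0 is the state immediately after the attacked edges are removed,
    before any overload failure; its ``failed_edges`` is empty.
    """

    failed_edges: frozenset[Edge]
    cumulative_failed: int
    n_drivers: int
    scc_edges: int


@dataclass(frozen=True)
class CascadeTrace:
    attacked: frozenset[Edge]
    stages: tuple[CascadeStage, ...]
    final_graph: DirectedGraph
    terminated: bool = True

    @property
    def total_failed(self) -> int:
        """Edges failed by overload; excludes the initially attacked ones."""
        return self.stages[-1].cumulative_failed

    @cached_property
    def cascade_failed_edges(self) -> frozenset[Edge]:
        out: set[Edge] = set()
        for st in self.stages:
            out |= st.failed_edges
        return frozenset(out)

    @property
    def all_failed_edges(self) -> frozenset[Edge]:
        """Attacked plus overload-failed edges."""
        return self.attacked | self.cascade_failed_edges


def run_cascade(
    graph: DirectedGraph,
    capacities: CapacityMap,
    removed_edges: Iterable[Edge],
    fractional: bool = False,
    largest_scc_only: bool = False,
) -> CascadeTrace:
    """Iterate the overload dynamics until no edge exceeds its capacity.

    Per stage: delete the current failure set, recompute all loads on the
    residual graph, fail every edge with ``load > capacity`` (strict; at
    ``alpha = 0`` an edge whose load did not grow survives), and record the
    driver-node count and SCC edge count.  Each stage removes at least one
    edge, so at most ``M`` stages occur.
    """
    attacked = frozenset(removed_edges)
    residual = graph.remove_edges(attacked)
    stages = [
        CascadeStage(
            frozenset(),
            0,
            driver_report(residual).n_drivers,
            scc_edge_count(residual, largest_scc_only),
        )
    ]
    cumulative = 0
    for _ in range(graph.M):
        loads = compute_loads(residual, fractional)
        overloaded = frozenset(e for e in residual.edges if loads[e] > capacities[e])
        if not overloaded:
            break
        residual = residual.remove_edges(overloaded)
        cumulative += len(overloaded)
        stages.append(
            CascadeStage(
                overloaded,
                cumulative,
                driver_report(residual).n_drivers,
                scc_edge_count(residual, largest_scc_only),
            )
        )
    return CascadeTrace(attacked, tuple(stages), residual)
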