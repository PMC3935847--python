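"""Edge-attack strategies: random (RA), intentional (IA) and highest-load.

RA removes a uniform random fraction of edges; IA removes edges in
descending order of their *initial* loads (the ranking basis is fixed by the
intact graph — edges are removed in one batch, no re-ranking between
removals).  The single highest-load-edge trigger is IA with one edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .graph_core import DirectedGraph, Edge

__all__ = [
    "AttackSpec",
    "select_edges_random",
    "select_edges_intentional",
    "select_highest_load_edge",
    "select_edges",
]

RANDOM = "RA"
INTENTIONAL = "IA"
HIGHEST = "highest"


@dataclass(frozen=True)
class AttackSpec:
    """Strategy + removal fraction + seed; fully determines the removed set."""

    strategy: str
    f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in (RANDOM, INTENTIONAL, HIGHEST):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("removal fraction f must lie in [0, 1]")


def _n_removed(f: float, m: int) -> int:
    """round(f*M), half away from zero, at least 1 when f > 0."""
    if f == 0.0:
        return 0
    return max(1, int(math.floor(f * m + 0.5)))


def select_edges_random(graph: DirectedGraph, f: float, seed: int) -> frozenset[Edge]:
    """Uniform sample without replacement of ``round(f * M)`` edges."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("removal fraction f must lie in [0, 1]")
    if graph.M < 1:
        raise ValueError("graph has no edges to attack")
    k = _n_removed(f, graph.M)
    rng = np.random.default_rng(seed)
    idx = rng.choice(graph.M, size=k, replace=False)
    return frozenset(graph.edges[i] for i in idx)


def select_edges_intentional(
    graph: DirectedGraph, loads: Mapping[Edge, float], f: float, seed: int
) -> frozenset[Edge]:
    """The ``round(f * M)`` edges of highest initial load.

    Ties at the load cutoff are broken uniformly at random with ``seed``
    (independent of input edge order); edges strictly above the cutoff are
    always included.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("removal fraction f must lie in [0, 1]")
    if graph.M < 1:
        raise ValueError("graph has no edges to attack")
    k = _n_removed(f, graph.M)
    if k == 0:
        return frozenset()
    load_arr = np.asarray([loads[e] for e in graph.edges])
    cutoff = np.sort(load_arr)[::-1][k - 1]
    above = [e for e, l in zip(graph.edges, load_arr) if l > cutoff]
    ties = [e for e, l in zip(graph.edges, load_arr) if l == cutoff]
    need = k - len(above)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ties), size=need, replace=False)
    return frozenset(above) | frozenset(ties[i] for i in pick)


def select_highest_load_edge(
    graph: DirectedGraph, loads: Mapping[Edge, float], seed: int
) -> frozenset[Edge]:
    """The single highest-load edge (maximal-load ties broken by seed)."""
    if graph.M < 1:
        raise ValueError("graph has no edges to attack")
    load_arr = np.asarray([loads[e] for e in graph.edges])
    top = load_arr.max()
    ties = [e for e, l in zip(graph.edges, load_arr) if l == top]
    rng = np.random.default_rng(seed)
    return frozenset({ties[int(rng.integers(len(ties)))]})


def select_edges(
    graph: DirectedGraph, loads: Mapping[Edge, float] | None, spec: AttackSpec
) -> frozenset[Edge]:
    """Dispatch on ``spec.strategy`` (loads required for IA / highest)."""
    if spec.strategy == RANDOM:
        return select_edges_random(graph, spec.f, spec.seed)
    if loads is None:
        raise ValueError(f"strategy {spec.strategy} requires initial loads")
    if spec.strategy == INTENTIONAL:
        return select_edges_intentional(graph, loads, spec.f, spec.seed)
    return select_highest_load_edge(graph, loads, spec.seed)
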