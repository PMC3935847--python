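"""Synthetic directed-network generators and deterministic toy fixtures.

Two random ensembles are provided, emulating the degree regimes of the real
systems this kind of analysis is run on (peer-to-peer overlays, neural wiring,
food webs): directed Erdős–Rényi graphs with a target mean degree, and
directed scale-free graphs built with the static model, which gives
independent control of the power-law exponent ``gamma`` and the mean degree.

Degree convention: ``<k> := M / N`` (average out-degree = average in-degree),
so ER uses edge probability ``p = <k>/(N-1)`` and the scale-free generator
draws ``M = round(N * <k>)`` distinct edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graph_core import DirectedGraph, Edge

__all__ = ["GeneratorSpec", "generate", "generate_er", "generate_sf", "toy_fixture"]

_MAX_SF_ROUNDS = 500


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of one synthetic-network draw.

    Same spec + same seed always yields the identical graph.

    Parameters
    ----------
    model
        ``"er"`` (Erdős–Rényi) or ``"sf"`` (scale-free, static model).
    n
        Node count (>= 2).
    mean_degree
        Target ``<k> = M/N``; may be 0 for a degenerate edgeless ER draw.
    gamma
        Power-law exponent of the in/out degree distributions (SF only;
        must exceed 2 for a finite mean).
    seed
        Master seed of the single per-realization random stream.
    """

    model: Literal["er", "sf"]
    n: int
    mean_degree: float
    gamma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("er", "sf"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.mean_degree < 0:
            raise ValueError("mean_degree must be >= 0")
        if self.model == "sf":
            if self.gamma is None or self.gamma <= 2:
                raise ValueError("scale-free model requires gamma > 2")
            if self.mean_degree == 0:
                raise ValueError("scale-free model requires mean_degree > 0")


def generate(spec: GeneratorSpec) -> DirectedGraph:
    """Dispatch to the generator named by ``spec.model``."""
    return generate_er(spec) if spec.model == "er" else generate_sf(spec)


def generate_er(spec: GeneratorSpec) -> DirectedGraph:
    """Directed G(N, p) with ``p = mean_degree / (N - 1)``.

    Every ordered pair ``(i, j)``, ``i != j``, receives an edge independently
    with probability ``p``; the realized ``M/N`` is an unbiased estimate of
    ``mean_degree``.
    """
    if spec.model != "er":
        raise ValueError("spec.model must be 'er'")
    n = spec.n
    p = spec.mean_degree / (n - 1)
    if p > 1:
        raise ValueError(f"mean_degree {spec.mean_degree} needs p <= 1 at N={n}")
    rng = np.random.default_rng(spec.seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    pairs = np.argwhere(mask)  # row-major order -> deterministic edge order
    edges = tuple((int(u), int(v)) for u, v in pairs)
    return DirectedGraph(n, edges)


def generate_sf(spec: GeneratorSpec) -> DirectedGraph:
    """Directed scale-free graph via the static model.

    Node ``i`` carries weight ``w_i = (i + 1)^(-1/(gamma-1))``;
    ``M = round(N * mean_degree)`` distinct edges are drawn by sampling source
    and target independently proportional to the weights, rejecting self-loops
    and duplicates.  Both the in- and out-degree tails then follow a power law
    with exponent ``gamma`` asymptotically.
    """
    if spec.model != "sf":
        raise ValueError("spec.model must be 'sf'")
    n = spec.n
    m_target = int(round(n * spec.mean_degree))
    if m_target > n * (n - 1):
        raise ValueError(f"requested M={m_target} exceeds N(N-1)={n * (n - 1)}")
    weights = np.arange(1, n + 1, dtype=float) ** (-1.0 / (spec.gamma - 1.0))
    probs = weights / weights.sum()
    rng = np.random.default_rng(spec.seed)
    seen: set[Edge] = set()
    edges: list[Edge] = []
    for _ in range(_MAX_SF_ROUNDS):
        need = m_target - len(edges)
        if need <= 0:
            break
        batch = max(2 * need, 128)
        us = rng.choice(n, size=batch, p=probs)
        vs = rng.choice(n, size=batch, p=probs)
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v or (u, v) in seen:
                continue
            seen.add((u, v))
            edges.append((u, v))
            if len(edges) == m_target:
                break
    else:
        raise RuntimeError(
            f"rejection sampling stalled after {_MAX_SF_ROUNDS} rounds "
            f"({len(edges)}/{m_target} edges); graph too dense for the weights"
        )
    return DirectedGraph(n, tuple(edges))


# -- deterministic toy fixtures ------------------------------------------

#: Hand-built graphs used in docs and tests.  "matching_demo" contains a
#: nontrivial SCC and all three controllability edge categories (verified by
#: the brute-force classification oracle in the test suite): the 3-cycle
#: 0->1->2->0 feeds the chain 2->3->4->5 whose shortcut 2->4 is redundant
#: and whose links 3->4, 4->5 are critical; node 6 receives ordinary edges
#: from 0 and 1 and feeds 7 through the critical edge 6->7.
_FIXTURES: dict[str, tuple[int, tuple[Edge, ...]]] = {
    "path3": (3, ((0, 1), (1, 2))),
    "cycle3": (3, ((0, 1), (1, 2), (2, 0))),
    "star_out5": (5, ((0, 1), (0, 2), (0, 3), (0, 4))),
    "matching_demo": (
        8,
        (
            (0, 1),
            (1, 2),
            (2, 0),
            (2, 3),
            (3, 4),
            (2, 4),
            (4, 5),
            (0, 6),
            (1, 6),
            (6, 7),
        ),
    ),
}


def toy_fixture(name: str) -> DirectedGraph:
    """Return a small deterministic graph from the fixture catalogue."""
    try:
        n, edges = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return DirectedGraph(n, edges)
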