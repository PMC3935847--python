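"""Brute-force oracles: exhaustive or networkx-based reference computations.

These deliberately share no code with the package implementation paths they
check: matchings are enumerated by include/exclude recursion, loads by
enumerating every shortest path with networkx, SCCs by pairwise reachability.
Only usable on small graphs.
"""

from __future__ import annotations

import networkx as nx


def enumerate_maximum_matchings(edges):
    """(max matching size, list of all maximum matchings as frozensets)."""
    edges = list(edges)
    best = {"size": 0, "members": [frozenset()]}

    def rec(i, used_s, used_t, cur):
        if i == len(edges):
            if len(cur) > best["size"]:
                best["size"] = len(cur)
                best["members"] = [frozenset(cur)]
            elif len(cur) == best["size"]:
                best["members"].append(frozenset(cur))
            return
        u, v = edges[i]
        if u not in used_s and v not in used_t:
            cur.append((u, v))
            rec(i + 1, used_s | {u}, used_t | {v}, cur)
            cur.pop()
        rec(i + 1, used_s, used_t, cur)

    rec(0, frozenset(), frozenset(), [])
    return best["size"], best["members"]


def brute_driver_count(n, edges):
    size, _ = enumerate_maximum_matchings(edges)
    return max(n - size, 1)


def brute_classify(edges):
    """Per-edge category from full enumeration of maximum matchings.

    critical = in every maximum matching (removal must shrink the matching),
    redundant = in none, ordinary = in some but not all.
    """
    _, maxms = enumerate_maximum_matchings(edges)
    out = {}
    for e in edges:
        hits = sum(1 for m in maxms if e in m)
        if hits == len(maxms):
            out[e] = "critical"
        elif hits == 0:
            out[e] = "redundant"
        else:
            out[e] = "ordinary"
    return out


def brute_loads(n, edges, fractional=False):
    """Edge loads by enumerating every shortest path of every ordered pair."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    loads = {e: 0.0 for e in edges}
    for s in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, s)
        for t in lengths:
            if t == s:
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            w = 1.0 / len(paths) if fractional else 1.0
            for path in paths:
                for e in zip(path[:-1], path[1:]):
                    loads[e] += w
    return loads


def brute_scc_edge_count(n, edges, largest_only=False):
    """SCC edge count from pairwise reachability (no Tarjan)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    reach = {u: set(nx.descendants(g, u)) | {u} for u in g.nodes}
    comps = []
    assigned = set()
    for u in g.nodes:
        if u in assigned:
            continue
        comp = {v for v in reach[u] if u in reach[v]}
        assigned |= comp
        comps.append(comp)
    nontrivial = [c for c in comps if len(c) >= 2]
    if largest_only:
        if not nontrivial:
            return 0
        nontrivial = [max(nontrivial, key=len)]
    return sum(
        1 for u, v in edges if any(u in c and v in c for c in nontrivial)
    )


def random_small_graph(rng, n_max=7, p=0.3):
    """A random directed graph as (n, edge tuple) for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    edges = tuple(
        (u, v)
        for u in range(n)
        for v in range(n)
        if u != v and rng.random() < p
    )
    return n, edges
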