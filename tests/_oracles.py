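"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's matching machinery: the maximum
matching is found by exhaustive enumeration over assignments of out-copies
to in-copies (bitmask recursion over all partial matchings), so agreement
with the Hopcroft-Karp-based implementation is a genuine cross-check.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx
import numpy as np


def brute_max_matching(edges, nodes):
    """Maximum matching cardinality of the bipartite lift by enumeration.

    ``edges`` are directed (u, v) pairs over ``nodes``; out-copy of each
    node may match the in-copy of any successor.  All partial assignments
    are explored (memoized on the set of used in-copies).
    """
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [[] for _ in nodes]
    for u, v in edges:
        adj[idx[u]].append(idx[v])

    @lru_cache(maxsize=None)
    def best(i: int, used_mask: int) -> int:
        if i == len(nodes):
            return 0
        out = best(i + 1, used_mask)  # leave out-copy i unmatched
        for j in adj[i]:
            if not used_mask & (1 << j):
                out = max(out, 1 + best(i + 1, used_mask | (1 << j)))
        return out

    result = best(0, 0)
    best.cache_clear()
    return result


def brute_mdns(edges, nodes) -> int:
    """MDNS size from the enumeration matching: max(N - |M*|, 1)."""
    n = len(set(nodes))
    if n == 0:
        raise ValueError("empty graph")
    return max(n - brute_max_matching(tuple(edges), tuple(sorted(set(nodes)))), 1)


def brute_critical(edges, nodes):
    """Critical nodes by single deletion against the enumeration oracle."""
    nodes = sorted(set(nodes))
    base = brute_mdns(edges, nodes)
    crit = set()
    for v in nodes:
        rest = [n for n in nodes if n != v]
        kept = [(a, b) for a, b in edges if a != v and b != v]
        if brute_mdns(kept, rest) > base:
            crit.add(v)
    return crit


def random_digraph(rng: np.random.Generator, n_max: int = 8):
    """A random directed graph (no self-loops) for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.choice([0.1, 0.2, 0.3, 0.4, 0.5]))
    nodes = [f"n{i}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g
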