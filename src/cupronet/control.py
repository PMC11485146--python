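"""Structural controllability: minimum driver node sets and critical nodes.

A directed network can be steered from any state to any other by external
signals injected at a minimum driver node set (MDNS).  By the structural
controllability correspondence, the MDNS size of a directed graph on N
nodes equals N - |M*| where M* is a maximum matching of the graph's
bipartite lift, floored at 1 (a perfectly matched network still needs one
control input).  Unmatched in-copies in the lift identify one witness
driver set.

A node is *critical* when deleting it (with all incident edges) strictly
increases the MDNS size of the remaining network: the network becomes
harder to control without it.  Criticality is evaluated globally, one node
at a time, against the intact network's MDNS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .network import GeneNetwork

__all__ = [
    "ControlResult",
    "bipartite_lift",
    "maximum_matching",
    "mdns_size",
    "driver_nodes",
    "critical_nodes",
]


@dataclass
class ControlResult:
    """MDNS size, one driver-set witness, and per-node criticality classes."""

    mdns_size: int
    driver_nodes: frozenset
    node_class: Mapping

    @property
    def critical(self) -> frozenset:
        return frozenset(n for n, c in self.node_class.items() if c == "critical")


def _as_digraph(g) -> nx.DiGraph:
    if isinstance(g, GeneNetwork):
        return g.graph
    if isinstance(g, nx.DiGraph):
        return g
    raise TypeError("expected a GeneNetwork or networkx.DiGraph")


def bipartite_lift(g) -> nx.Graph:
    """Bipartite representation of a directed graph.

    Each node u contributes an out-copy ("out", u) and an in-copy
    ("in", u); each directed edge u -> v contributes the undirected edge
    ("out", u) -- ("in", v).
    """
    dg = _as_digraph(g)
    b = nx.Graph()
    for node in dg.nodes:
        b.add_node(("out", node), bipartite=0)
        b.add_node(("in", node), bipartite=1)
    for u, v in dg.edges:
        b.add_edge(("out", u), ("in", v))
    return b


def maximum_matching(b: nx.Graph) -> dict:
    """Maximum-cardinality matching of a bipartite lift.

    Hopcroft-Karp over lexicographically sorted out-copies; the matched
    cardinality is order-invariant even though the witness is not.  Returns
    the networkx matching dict (both directions included).
    """
    tops = sorted((n for n, d in b.nodes(data=True) if d.get("bipartite") == 0),
                  key=lambda n: str(n[1]))
    return nx.bipartite.hopcroft_karp_matching(b, top_nodes=tops)


def mdns_size(g) -> int:
    """Minimum driver node set size: max(N - |M*|, 1)."""
    dg = _as_digraph(g)
    n = dg.number_of_nodes()
    if n == 0:
        raise ValueError("network has no nodes")
    matching = maximum_matching(bipartite_lift(dg))
    m_star = len(matching) // 2
    return max(n - m_star, 1)


def driver_nodes(g) -> frozenset:
    """One witness driver set: nodes whose in-copy is unmatched.

    When the matching is perfect (MDNS floored at 1), the lexicographically
    smallest node is returned as the single driver by convention.
    """
    dg = _as_digraph(g)
    if dg.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    matching = maximum_matching(bipartite_lift(dg))
    unmatched = [v for v in dg.nodes if ("in", v) not in matching]
    if unmatched:
        return frozenset(unmatched)
    return frozenset([min(dg.nodes, key=str)])


def critical_nodes(g) -> ControlResult:
    """Classify every node as critical or non-critical by single removal.

    Node v is critical iff mdns_size(g - v) > mdns_size(g), where g - v is
    the network with v and all incident edges removed.  Requires at least 2
    nodes so removal leaves a non-empty network.
    """
    dg = _as_digraph(g)
    if dg.number_of_nodes() < 2:
        raise ValueError("criticality needs at least 2 nodes")
    base = mdns_size(dg)
    classes = {}
    for v in dg.nodes:
        reduced = nx.restricted_view(dg, [v], [])
        classes[v] = "critical" if mdns_size(reduced) > base else "non_critical"
    return ControlResult(mdns_size=base, driver_nodes=driver_nodes(dg), node_class=classes)
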