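"""Structural controllability of the directed functional network.

Following the maximum-matching characterization of structural
controllability for linear systems on directed graphs: the minimum number
of external driver nodes equals ``max(N - M*, 1)`` where ``M*`` is the
size of a maximum matching of the digraph (edges sharing no start vertex
and no end vertex).  The matching is found by turning the digraph into an
undirected bipartite graph — one left copy of every node for its outgoing
role, one right copy for its incoming role — and running Hopcroft-Karp.
If a perfect matching exists a single driver suffices; otherwise the
unmatched right-copy nodes are the drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.bipartite import hopcroft_karp_matching


@dataclass
class ControlReport:
    n_nodes: int
    matching_size: int
    n_drivers: int
    drivers: list


def to_bipartite(digraph: nx.DiGraph, include_self_loops: bool = True) -> nx.Graph:
    """Bipartite out/in split of a digraph.

    Left node ``("out", u)`` and right node ``("in", v)`` are joined iff
    the digraph has ``u -> v``.  Self-loops become ``("out", u)-("in", u)``
    edges when ``include_self_loops`` (a node with a retained self-kernel
    can match itself).
    """
    b = nx.Graph()
    for u in digraph.nodes:
        b.add_node(("out", u), bipartite=0)
        b.add_node(("in", u), bipartite=1)
    for u, v in digraph.edges:
        if u == v and not include_self_loops:
            continue
        b.add_edge(("out", u), ("in", v))
    return b


def maximum_matching(bipartite: nx.Graph) -> dict:
    """Maximum-cardinality matching (Hopcroft-Karp) of the out/in graph.

    Returns the matching as a dict containing both directions, as
    networkx does.
    """
    top = [n for n in bipartite.nodes if n[0] == "out"]
    return hopcroft_karp_matching(bipartite, top_nodes=top)


def min_driver_nodes(
    digraph: nx.DiGraph, include_self_loops: bool = True
) -> ControlReport:
    """Minimum driver-node set of a directed network.

    ``N_i = max(N - M*, 1)``: with a perfect matching one node can steer
    the whole network; otherwise every node whose incoming copy is
    unmatched must be driven directly.  The driver list is sorted for
    determinism (any single node stands in when the matching is perfect).
    """
    n = digraph.number_of_nodes()
    if n < 1:
        raise ValueError("graph must have at least one node")
    b = to_bipartite(digraph, include_self_loops=include_self_loops)
    matching = maximum_matching(b)
    m_star = sum(1 for k in matching if k[0] == "out")
    n_drivers = max(n - m_star, 1)
    unmatched = sorted(
        u for u in digraph.nodes if ("in", u) not in matching
    )
    drivers = unmatched if unmatched else sorted(digraph.nodes)[:1]
    return ControlReport(
        n_nodes=n, matching_size=m_star, n_drivers=n_drivers, drivers=drivers
    )
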