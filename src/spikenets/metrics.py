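"""Small-world metrics on binary graphs.

All small-world quantities are computed on the binarized, symmetrized
graph (direction is only kept for controllability).  Two metrics are
provided:

* ``S_w = (C/C_r) / (L/L_r)`` against Erdos-Renyi references with the
  same node and edge counts; values above 1 suggest small-world
  structure, but S_w is unbounded and grows with network size.
* ``omega = L_r/L - C/C_l`` which in addition uses the clustering of a
  matched ring lattice ``C_l``.  omega near 0 means small-world, near +1
  random-like, near -1 lattice-like, and it is far less size-sensitive.

Path lengths are averaged over unordered pairs of the largest connected
component.  Dense-adjacency variants of the two base measures are
provided for simulation loops where networkx overhead dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path


@dataclass
class SmallWorldReport:
    n_nodes: int
    n_edges: int
    mean_degree: float
    avg_path_length: float
    avg_clustering: float
    c_random: float
    l_random: float
    c_lattice: float
    s_w: float
    omega: float
    flags: list[str]


def _as_undirected(net: nx.Graph) -> nx.Graph:
    g = net.to_undirected() if net.is_directed() else net
    return nx.Graph(g)


def degree_distribution(net: nx.Graph) -> dict[int, float]:
    """Empirical degree distribution P(k) on the symmetrized graph."""
    g = _as_undirected(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degs = np.array([d for _, d in g.degree()])
    ks, counts = np.unique(degs, return_counts=True)
    return {int(k): float(c) / degs.size for k, c in zip(ks, counts)}


def average_path_length(net: nx.Graph) -> float:
    """Mean shortest-path hop count over unordered pairs of the largest
    connected component of the symmetrized graph."""
    g = _as_undirected(net)
    if g.number_of_nodes() < 2:
        raise ValueError("average path length needs at least 2 nodes")
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        raise ValueError("largest component is a single node")
    return float(nx.average_shortest_path_length(g.subgraph(comp)))


def average_clustering(net: nx.Graph) -> float:
    """Mean local clustering coefficient; degree<2 nodes contribute 0."""
    g = _as_undirected(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(g))


# ---------------------------------------------------------------------------
# dense-adjacency fast paths (used heavily by the spatial simulations)


def average_path_length_dense(adj: np.ndarray) -> float:
    """As :func:`average_path_length`, on a symmetric 0/1 adjacency matrix."""
    a = np.asarray(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("average path length needs at least 2 nodes")
    sp = csr_matrix(a)
    ncomp, labels = connected_components(sp, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        keep = labels == np.argmax(sizes)
        if keep.sum() < 2:
            raise ValueError("largest component is a single node")
        a = a[np.ix_(keep, keep)]
        sp = csr_matrix(a)
    d = shortest_path(sp, method="D", unweighted=True, directed=False)
    iu = np.triu_indices_from(d, k=1)
    return float(d[iu].mean())


def average_clustering_dense(adj: np.ndarray) -> float:
    """As :func:`average_clustering`, on a symmetric 0/1 adjacency matrix."""
    a = np.asarray(adj, dtype=float)
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a)  # 2 * triangles through each node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, tri / denom, 0.0)
    return float(local.mean())


# ---------------------------------------------------------------------------
# reference graphs


def ring_lattice(n: int, m: int) -> nx.Graph:
    """Deterministic ring lattice on ``n`` nodes with exactly ``m`` edges.

    Edges are added ring-wise by increasing neighbor offset (all offset-1
    edges, then offset-2, ...), the last partial offset filled from node 0
    upward.  This is the regular-lattice reference for the omega metric.
    """
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValueError("too many edges for a simple graph")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    remaining = m
    offset = 1
    while remaining > 0 and offset <= n // 2:
        ring = [(i, (i + offset) % n) for i in range(n)]
        if offset == n / 2:  # antipodal offset gives each edge twice
            ring = ring[: n // 2]
        take = ring[: min(remaining, len(ring))]
        g.add_edges_from(take)
        remaining -= len(take)
        offset += 1
    return g


def reference_graphs(
    n: int, m: int, reps: int = 20, seed: int | None = None
) -> tuple[float, float, float]:
    """Random and lattice reference values ``(C_r, L_r, C_l)``.

    ``C_r`` and ``L_r`` are means over ``reps`` Erdos-Renyi G(n, m)
    samples (path length on the largest component when a sample is
    disconnected); ``C_l`` is the clustering coefficient of the matched
    ring lattice and is deterministic.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        cs.append(nx.average_clustering(g))
        comp = max(nx.connected_components(g), key=len)
        if len(comp) >= 2:
            ls.append(nx.average_shortest_path_length(g.subgraph(comp)))
    if not ls:
        raise ValueError("random references have no component with >= 2 nodes")
    c_l = average_clustering(ring_lattice(n, m))
    return float(np.mean(cs)), float(np.mean(ls)), c_l


def small_worldness_S(c: float, l: float, c_r: float, l_r: float) -> float:
    """``S_w = (C/C_r) / (L/L_r)``; > 1 flags small-world structure."""
    if min(c, l, c_r, l_r) <= 0:
        raise ValueError("all inputs must be positive")
    return (c / c_r) / (l / l_r)


def small_worldness_omega(c: float, l: float, c_l: float, l_r: float) -> float:
    """``omega = L_r/L - C/C_l``; ~0 small-world, ~1 random, ~-1 lattice."""
    if c_l <= 0:
        raise ValueError("lattice clustering must be positive")
    if l <= 0:
        raise ValueError("path length must be positive")
    return l_r / l - c / c_l


def small_world_report(
    net: nx.Graph, reps: int = 20, seed: int | None = None
) -> SmallWorldReport:
    """Compute both small-world metrics with matched reference graphs."""
    g = _as_undirected(net)
    n, m = g.number_of_nodes(), g.number_of_edges()
    flags: list[str] = []
    lbar = average_path_length(g)
    cbar = average_clustering(g)
    if len(max(nx.connected_components(g), key=len)) < n:
        flags.append("graph disconnected; L on largest component")
    c_r, l_r, c_l = reference_graphs(n, m, reps=reps, seed=seed)
    s_w = small_worldness_S(cbar, lbar, c_r, l_r) if min(cbar, c_r) > 0 else float("nan")
    if min(cbar, c_r) <= 0:
        flags.append("zero clustering; S_w undefined")
    omega = small_worldness_omega(cbar, lbar, c_l, l_r) if c_l > 0 else float("nan")
    if c_l <= 0:
        flags.append("lattice reference has no triangles; omega undefined")
    degs = [d for _, d in g.degree()]
    return SmallWorldReport(
        n_nodes=n,
        n_edges=m,
        mean_degree=float(np.mean(degs)),
        avg_path_length=lbar,
        avg_clustering=cbar,
        c_random=c_r,
        l_random=l_r,
        c_lattice=c_l,
        s_w=s_w,
        omega=omega,
        flags=flags,
    )


def omega_dense(adj: np.ndarray, reps: int = 20, seed: int | None = None) -> float:
    """``omega`` for a dense symmetric adjacency, using the fast paths.

    The Erdos-Renyi path-length reference is still sampled via networkx
    graph generation but measured with the dense routines.
    """
    a = np.asarray(adj)
    n = a.shape[0]
    m = int(np.triu(a, 1).sum())
    lbar = average_path_length_dense(a)
    cbar = average_clustering_dense(a)
    rng = np.random.default_rng(seed)
    ls = []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        ls.append(average_path_length_dense(nx.to_numpy_array(g)))
    c_l = average_clustering_dense(nx.to_numpy_array(ring_lattice(n, m)))
    if c_l <= 0:
        return float("nan")
    return small_worldness_omega(cbar, lbar, c_l, float(np.mean(ls)))
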