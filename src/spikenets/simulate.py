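"""Distance-dependent 3D network models and virtual multi-electrode sampling.

Neurons are placed uniformly in a cuboid of cortical tissue (default
780 x 320 x 100 um, the tissue volume spanned by a 4-shank probe with
~200 um inter-shank spacing and ~50 um recording columns).  Connections
form with a probability that decays with inter-somatic distance:

* threshold model — Bernoulli(P_in) for pairs within distance ``l``,
  Bernoulli(P_out) beyond it (normally ``P_in > P_out``);
* model 1 — ``P(d) = P_0 + alpha * lam**(d/d_unit)``: geometric decay to
  a baseline, ``alpha`` sets the short-range (initial-state) probability,
  larger ``lam`` extends long-range connectivity;
* model 2 — ``P(d) = P_1 + gamma / (1 + beta*d/d_unit)``: hyperbolic
  decay with a heavier tail, i.e. more tolerance for long-range
  connections; ``gamma`` sets the initial state, larger ``beta`` lowers
  the curve at every positive distance.

Virtual electrodes sample the induced subgraph of all neurons within a
radius ``l'`` (default 50 um, an extracellular detection range) of any
electrode tip — the sampled network (SN) whose small-world-ness is
compared against the original network (ON).

A small genetic algorithm fits the threshold-model parameters to an
experimentally observed (path length, clustering) pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .metrics import average_clustering_dense, average_path_length_dense

#: Cuboid of tissue sampled by a 4-shank probe, in micrometers.
DEFAULT_SPACE = (780.0, 320.0, 100.0)

#: Extracellular detection radius around an electrode tip, micrometers.
DEFAULT_SAMPLING_RADIUS = 50.0

#: Distance scale of the parametric decay models, micrometers.
DEFAULT_DISTANCE_UNIT = 50.0


@dataclass
class SpatialNetwork:
    """Neuron positions plus an undirected connectivity matrix."""

    positions: np.ndarray  # (N, 3), um
    space: tuple[float, float, float]
    adjacency: np.ndarray  # (N, N) bool, symmetric, zero diagonal
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    @property
    def edge_density(self) -> float:
        n = self.n_neurons
        return self.n_edges / (n * (n - 1) / 2)

    def graph(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency.astype(int))


@dataclass
class ElectrodeArray:
    positions: np.ndarray  # (K, 3), um
    radius: float  # sampling radius l', um

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one electrode")
        if self.radius <= 0:
            raise ValueError("sampling radius must be positive")


def place_neurons(
    n: int, space: tuple[float, float, float] = DEFAULT_SPACE, seed=None
) -> np.ndarray:
    """Uniform i.i.d. neuron positions inside the cuboid."""
    if n < 2:
        raise ValueError("need at least 2 neurons")
    dims = np.asarray(space, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("space dimensions must be positive")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, dims, size=(n, 3))


def _bernoulli_adjacency(prob_upper: np.ndarray, n: int, rng) -> np.ndarray:
    """Symmetric adjacency from per-pair probabilities (condensed order)."""
    draws = rng.random(prob_upper.shape) < prob_upper
    adj = squareform(draws).astype(bool)
    return adj


def connect_threshold(
    positions: np.ndarray,
    l: float,
    p_in: float,
    p_out: float,
    seed=None,
    space: tuple[float, float, float] = DEFAULT_SPACE,
) -> SpatialNetwork:
    """Threshold model: Bernoulli(P_in) within distance ``l``, else P_out."""
    if not 0 <= p_out <= 1 or not 0 <= p_in <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    if l <= 0:
        raise ValueError("distance threshold must be positive")
    rng = np.random.default_rng(seed)
    d = pdist(positions)
    prob = np.where(d <= l, p_in, p_out)
    adj = _bernoulli_adjacency(prob, positions.shape[0], rng)
    return SpatialNetwork(
        positions=np.asarray(positions, float),
        space=tuple(space),
        adjacency=adj,
        params={"model": "threshold", "l": l, "p_in": p_in, "p_out": p_out},
        seed=seed,
    )


def connection_prob_model1(
    d, alpha: float, lam: float, p0: float = 0.0, d_unit: float = DEFAULT_DISTANCE_UNIT
):
    """Geometric-decay connection probability, clipped to [0, 1].

    At ``d = 0`` (with ``p0 = 0``) the probability is ``alpha``; it decays
    monotonically toward the baseline ``p0`` as ``d`` grows, with larger
    ``lam`` preserving more long-range probability.
    """
    if not 0 < alpha < 1 and alpha != 1:
        raise ValueError("alpha must be in (0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lam must be in (0, 1)")
    d = np.asarray(d, dtype=float)
    return np.clip(p0 + alpha * lam ** (d / d_unit), 0.0, 1.0)


def connection_prob_model2(
    d, beta: float, gamma: float, p1: float = 0.0, d_unit: float = DEFAULT_DISTANCE_UNIT
):
    """Hyperbolic-decay connection probability, clipped to [0, 1].

    At ``d = 0`` (with ``p1 = 0``) the probability is ``gamma``; for any
    finite distance it stays strictly above the asymptote ``p1`` — the
    heavier tail compared with the geometric model.  Larger ``beta``
    lowers the probability at every positive distance.
    """
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    d = np.asarray(d, dtype=float)
    return np.clip(p1 + gamma / (1.0 + beta * d / d_unit), 0.0, 1.0)


def connect_model1(
    positions, alpha, lam, p0=0.0, d_unit=DEFAULT_DISTANCE_UNIT, seed=None,
    space=DEFAULT_SPACE,
) -> SpatialNetwork:
    rng = np.random.default_rng(seed)
    prob = connection_prob_model1(pdist(positions), alpha, lam, p0, d_unit)
    adj = _bernoulli_adjacency(prob, positions.shape[0], rng)
    return SpatialNetwork(
        positions=np.asarray(positions, float), space=tuple(space), adjacency=adj,
        params={"model": "model1", "alpha": alpha, "lam": lam, "p0": p0,
                "d_unit": d_unit},
        seed=seed,
    )


def connect_model2(
    positions, beta, gamma, p1=0.0, d_unit=DEFAULT_DISTANCE_UNIT, seed=None,
    space=DEFAULT_SPACE,
) -> SpatialNetwork:
    rng = np.random.default_rng(seed)
    prob = connection_prob_model2(pdist(positions), beta, gamma, p1, d_unit)
    adj = _bernoulli_adjacency(prob, positions.shape[0], rng)
    return SpatialNetwork(
        positions=np.asarray(positions, float), space=tuple(space), adjacency=adj,
        params={"model": "model2", "beta": beta, "gamma": gamma, "p1": p1,
                "d_unit": d_unit},
        seed=seed,
    )


def calibrate_threshold(
    positions: np.ndarray, p_in: float, p_out: float, target_density: float
) -> float:
    """Distance threshold ``l`` giving the requested expected edge density.

    Solves ``P_in * F(l) + P_out * (1 - F(l)) = rho`` for the fraction
    ``F`` of pairs within ``l`` and returns the corresponding empirical
    quantile of the pairwise distances.
    """
    if p_in == p_out:
        raise ValueError("p_in == p_out: density does not depend on l")
    f = (target_density - p_out) / (p_in - p_out)
    if not 0 < f < 1:
        raise ValueError(
            f"target density {target_density} unreachable with "
            f"p_in={p_in}, p_out={p_out}"
        )
    return float(np.quantile(pdist(positions), f))


def place_electrodes(
    k: int,
    space: tuple[float, float, float] = DEFAULT_SPACE,
    seed=None,
    radius: float = DEFAULT_SAMPLING_RADIUS,
) -> ElectrodeArray:
    """Insert ``k`` electrodes uniformly at random into the cuboid."""
    if k < 1:
        raise ValueError("need at least one electrode")
    dims = np.asarray(space, dtype=float)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, dims, size=(k, 3))
    return ElectrodeArray(positions=pos, radius=radius)


def sample_network(
    snet: SpatialNetwork, array: ElectrodeArray
) -> tuple[np.ndarray, np.ndarray]:
    """Electrode-sampled (induced) subnetwork.

    The sampled set is every neuron within the array's radius of any
    electrode; the returned adjacency is the vertex-induced subgraph —
    exactly the edges of the original network between sampled neurons.
    Returns ``(sub_adjacency, sampled_indices)``.
    """
    d = cdist(snet.positions, array.positions).min(axis=1)
    idx = np.flatnonzero(d <= array.radius)
    if idx.size == 0:
        raise ValueError("no neuron within sampling radius of any electrode")
    return snet.adjacency[np.ix_(idx, idx)], idx


def calibrate_sampling_radius(
    positions: np.ndarray, electrode_positions: np.ndarray, n_target: int
) -> float:
    """Radius ``l'`` capturing ~``n_target`` neurons for this electrode set."""
    d = cdist(positions, np.atleast_2d(electrode_positions)).min(axis=1)
    n_target = int(np.clip(n_target, 1, d.size))
    return float(np.sort(d)[n_target - 1])


# ---------------------------------------------------------------------------
# genetic-algorithm pattern fitting


@dataclass
class PatternFit:
    p_in: float
    p_out: float
    l_quantile: float
    achieved_L: float
    achieved_C: float
    objective: float
    history: list[float]


def _pattern_objective(
    genes: np.ndarray,
    target_l: float,
    target_c: float,
    n: int,
    realizations: int,
    space,
    base_seed: int,
) -> tuple[float, float, float]:
    """Mean (L, C) over fixed-seed graph realizations plus squared error.

    Common random numbers: realization ``r`` always uses seed
    ``base_seed + r`` for both positions and edge draws, so the objective
    is a deterministic function of the genes and the GA surface is not
    re-randomized between generations.
    """
    p_in, p_out, lq = genes
    ls, cs = [], []
    for r in range(realizations):
        rng = np.random.default_rng(base_seed + r)
        pos = rng.uniform(0.0, np.asarray(space, float), size=(n, 3))
        d = pdist(pos)
        l = np.quantile(d, lq)
        prob = np.where(d <= l, p_in, p_out)
        adj = squareform(rng.random(d.shape) < prob).astype(float)
        try:
            ls.append(average_path_length_dense(adj))
        except ValueError:
            ls.append(n)  # disconnected down to singletons: worst case
        cs.append(average_clustering_dense(adj))
    lbar, cbar = float(np.mean(ls)), float(np.mean(cs))
    return (lbar - target_l) ** 2 + (cbar - target_c) ** 2, lbar, cbar


def fit_pattern_ga(
    target_l: float,
    target_c: float,
    n: int,
    generations: int = 60,
    pop: int = 40,
    seed: int | None = None,
    realizations: int = 5,
    space: tuple[float, float, float] = DEFAULT_SPACE,
) -> PatternFit:
    """Fit threshold-model parameters to a (path length, clustering) pattern.

    Optimizes ``(P_in, P_out, l-quantile)`` — the local-region size is a
    free gene alongside the two probabilities — by a small generational GA
    (tournament selection, blend crossover, Gaussian mutation, elitism),
    minimizing the squared deviation of the realization-averaged pattern
    from the target.  ``P_in >= P_out`` is enforced by repair.
    """
    if not 0 < target_c <= 1:
        raise ValueError("target clustering must be in (0, 1]")
    if target_l < 1:
        raise ValueError("target path length must be >= 1")
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(2**30))
    lo = np.array([0.0, 0.0, 0.05])
    hi = np.array([1.0, 1.0, 0.95])

    def repair(g):
        g = np.clip(g, lo, hi)
        if g[0] < g[1]:
            g[0], g[1] = g[1], g[0]
        return g

    population = [repair(rng.uniform(lo, hi)) for _ in range(pop)]
    cache: dict[tuple, tuple[float, float, float]] = {}

    def evaluate(g):
        key = tuple(np.round(g, 6))
        if key not in cache:
            cache[key] = _pattern_objective(
                g, target_l, target_c, n, realizations, space, base_seed
            )
        return cache[key]

    scored = [(evaluate(g), g) for g in population]
    history = []
    for _ in range(generations):
        scored.sort(key=lambda t: t[0][0])
        history.append(scored[0][0][0])
        elite = [g for _, g in scored[: max(2, pop // 10)]]
        children = list(elite)
        while len(children) < pop:
            # tournament of 3 for each parent
            pa = min(rng.choice(pop, 3), key=lambda i: scored[i][0][0])
            pb = min(rng.choice(pop, 3), key=lambda i: scored[i][0][0])
            w = rng.uniform(-0.25, 1.25, size=3)  # blend crossover
            child = w * scored[pa][1] + (1 - w) * scored[pb][1]
            if rng.random() < 0.6:
                child = child + rng.normal(0.0, 0.08, size=3)
            children.append(repair(child))
        scored = [(evaluate(g), g) for g in children]
    scored.sort(key=lambda t: t[0][0])
    (obj, lbar, cbar), best = scored[0]
    history.append(obj)
    return PatternFit(
        p_in=float(best[0]),
        p_out=float(best[1]),
        l_quantile=float(best[2]),
        achieved_L=lbar,
        achieved_C=cbar,
        objective=obj,
        history=history,
    )
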