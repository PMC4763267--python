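"""Spike-train and network I/O.

The central container is :class:`SpikeTrainSet`: per-neuron event times in
seconds together with a binned 0/1 matrix view.  Bins are half-open
``[k*dt, (k+1)*dt)``; multiple spikes falling into one bin clip to 1, i.e.
the binned view is a binary (spike / no-spike) train.

Networks travel either as GraphML or as a plain-text node/edge list that
preserves isolated nodes.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml

#: Directed binary functional-connectivity graph.  Node labels are neuron
#: ids; an optional ``region`` node attribute carries anatomical labels.
FunctionalNetwork = nx.DiGraph


class SpikeFileError(ValueError):
    """Raised on malformed spike-train files."""


@dataclass
class SpikeTrainSet:
    """Event times for a population of neurons plus a binned binary view.

    Parameters
    ----------
    neuron_ids : list of str
        Stable per-neuron labels, in presentation order.
    spike_times : list of ndarray
        Event times in seconds, one sorted array per neuron, all within
        ``[0, duration]``.
    duration : float
        Recording length in seconds.
    bin_width : float
        Width of the half-open bins used for the binary matrix view.
    """

    neuron_ids: list[str]
    spike_times: list[np.ndarray]
    duration: float
    bin_width: float = 0.01

    def __post_init__(self) -> None:
        if len(self.neuron_ids) != len(self.spike_times):
            raise ValueError("neuron_ids and spike_times length mismatch")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        clean = []
        for nid, t in zip(self.neuron_ids, self.spike_times):
            t = np.sort(np.asarray(t, dtype=float))
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"neuron {nid!r}: spike times outside [0, {self.duration}]"
                )
            clean.append(t)
        self.spike_times = clean

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.duration / self.bin_width))

    def counts(self) -> np.ndarray:
        """Spike count per neuron."""
        return np.array([t.size for t in self.spike_times])

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron in Hz (count / duration)."""
        return self.counts() / self.duration

    def binned(self) -> np.ndarray:
        """Binary ``(n_neurons, n_bins)`` matrix; entry 1 iff the neuron
        spiked at least once in the bin."""
        x = np.zeros((self.n_neurons, self.n_bins), dtype=np.uint8)
        nb = self.n_bins
        for i, t in enumerate(self.spike_times):
            idx = np.floor(t / self.bin_width).astype(int)
            idx = np.minimum(idx, nb - 1)  # t == duration lands in last bin
            x[i, idx] = 1
        return x

    def spike_bins(self, neuron: int | str) -> np.ndarray:
        """Sorted unique bin indices with at least one spike."""
        i = neuron if isinstance(neuron, int) else self.neuron_ids.index(neuron)
        idx = np.floor(self.spike_times[i] / self.bin_width).astype(int)
        return np.unique(np.minimum(idx, self.n_bins - 1))


def read_spike_tsv(
    path: str | Path,
    duration: float | None = None,
    bin_width: float = 0.01,
) -> SpikeTrainSet:
    """Read a two-column ``neuron_id <TAB> time_s`` table.

    A single header line is tolerated.  ``duration`` defaults to the
    latest spike time observed.
    """
    path = Path(path)
    per_neuron: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise SpikeFileError(f"{path}:{lineno}: expected 2 columns")
            nid, tstr = parts
            try:
                t = float(tstr)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise SpikeFileError(
                    f"{path}:{lineno}: non-numeric time {tstr!r}"
                ) from None
            if t < 0:
                raise SpikeFileError(f"{path}:{lineno}: negative time {t}")
            per_neuron.setdefault(nid, []).append(t)
    if not per_neuron:
        raise SpikeFileError(f"{path}: no spikes found")
    ids = list(per_neuron)
    times = [np.array(per_neuron[k]) for k in ids]
    if duration is None:
        duration = max(t.max() for t in times if t.size)
    return SpikeTrainSet(ids, times, duration=float(duration), bin_width=bin_width)


def write_spike_tsv(sts: SpikeTrainSet, path: str | Path) -> None:
    """Write the inverse of :func:`read_spike_tsv` (merged, time-sorted)."""
    rows = [
        (t, nid)
        for nid, times in zip(sts.neuron_ids, sts.spike_times)
        for t in times
    ]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("neuron_id\ttime_s\n")
        for t, nid in rows:
            fh.write(f"{nid}\t{t:.9f}\n")


def read_crcns_pair(
    res_path: str | Path,
    clu_path: str | Path,
    sample_rate_hz: float,
    bin_width: float = 0.01,
    drop_clusters: Sequence[int] = (0, 1),
) -> SpikeTrainSet:
    """Read paired cluster/timestamp files (hc-3 style).

    ``res`` holds one integer sample index per spike; ``clu`` holds the
    cluster count on its first line followed by one cluster label per
    spike.  Clusters in ``drop_clusters`` (conventionally noise and
    multi-unit artifact) are discarded.  ``sample_rate_hz`` converts
    sample indices to seconds and must be passed explicitly.
    """
    res = np.loadtxt(res_path, dtype=np.int64, ndmin=1)
    clu = np.loadtxt(clu_path, dtype=np.int64, ndmin=1)
    if clu.size != res.size + 1:
        raise SpikeFileError(
            "clu file must contain one leading cluster count plus one label per spike"
        )
    labels = clu[1:]
    times = res / float(sample_rate_hz)
    keep = ~np.isin(labels, list(drop_clusters))
    labels, times = labels[keep], times[keep]
    if labels.size == 0:
        raise SpikeFileError("no spikes left after dropping noise clusters")
    ids = [str(c) for c in np.unique(labels)]
    per = [times[labels == int(c)] for c in ids]
    return SpikeTrainSet(ids, per, duration=float(times.max()), bin_width=bin_width)


def filter_by_rate(sts: SpikeTrainSet, floor_hz: float) -> SpikeTrainSet:
    """Keep neurons with firing rate >= ``floor_hz``, preserving order.

    Low-rate units carry too few events to constrain their kernels; the
    default analysis floor is 0.5 Hz.
    """
    if floor_hz < 0:
        raise ValueError("floor_hz must be >= 0")
    keep = [i for i, r in enumerate(sts.rates()) if r >= floor_hz]
    return SpikeTrainSet(
        [sts.neuron_ids[i] for i in keep],
        [sts.spike_times[i] for i in keep],
        duration=sts.duration,
        bin_width=sts.bin_width,
    )


# ---------------------------------------------------------------------------
# network I/O


def write_network(net: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a network as GraphML or as a node/edge TSV.

    The TSV format writes every node on its own single-column line and
    every edge as ``u <TAB> v``, so isolated nodes survive a round trip.
    ``fmt`` defaults from the file suffix (.graphml vs anything else).
    """
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "tsv")
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# directed={int(net.is_directed())}\n")
            for n in net.nodes:
                fh.write(f"{n}\n")
            for u, v in net.edges:
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "tsv")
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    with open(path) as fh:
        first = fh.readline().strip()
        directed = True
        if first.startswith("# directed="):
            directed = bool(int(first.split("=")[1]))
            lines = fh.readlines()
        else:
            lines = [first + "\n"] + fh.readlines()
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            g.add_node(parts[0])
        else:
            g.add_edge(parts[0], parts[1])
    return g


# ---------------------------------------------------------------------------
# analysis configuration


@dataclass
class AnalysisConfig:
    """Bundle of tunable parameters for the reconstruction pipeline.

    Defaults: 10 ms bins, 50-bin (0.5 s) history, 3 Laguerre orders, decay
    grid 0.2-0.9, L1 penalty grid of 20 points log-spaced over
    [1e-5, 1e-1], 5-fold contiguous-block cross-validation and a 0.5 Hz
    firing-rate floor.
    """

    bin_width: float = 0.01
    memory_bins: int = 50
    basis_order: int = 3
    alpha_grid: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    zeta_grid: tuple[float, ...] = tuple(np.logspace(-5, -1, 20))
    cv_folds: int = 5
    rate_floor_hz: float = 0.5
    seed: int = 0
    simulator: dict = field(default_factory=dict)
    correction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alpha_grid or not self.zeta_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.rate_floor_hz < 0:
            raise ValueError("rate_floor_hz must be >= 0")
        self.alpha_grid = tuple(float(a) for a in self.alpha_grid)
        self.zeta_grid = tuple(float(z) for z in self.zeta_grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["alpha_grid"] = list(d["alpha_grid"])
        d["zeta_grid"] = [float(z) for z in d["zeta_grid"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
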