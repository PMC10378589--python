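"""Synthetic multichannel time series with known directed coupling.

Two generators are provided: the five-map coupled quadratic autoregressive
benchmark system with its fixed four-edge ground-truth graph, and a general
region-level generator that places the same weakly coupled nonlinear dynamics
on an arbitrary directed graph, emulating preprocessed resting-state
region-averaged MEG signals.  A helper averages raw channels into regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoupledMapConfig",
    "GroundTruthGraph",
    "RegionSeriesSet",
    "COUPLED_MAP_EDGES",
    "MEG_REGION_LABELS",
    "simulate_coupled_maps",
    "simulate_region_network",
    "average_channels_to_regions",
]

logger = logging.getLogger(__name__)

#: The 14 sensor-space brain-region labels (left/middle/right frontal, central,
#: parietal, occipital; left/right temporal).
MEG_REGION_LABELS = (
    "LF", "ZF", "RF", "LC", "ZC", "RC", "LT", "RT",
    "LP", "ZP", "RP", "LO", "ZO", "RO",
)

#: Directed couplings wired into the five-map benchmark (1-based labels).
COUPLED_MAP_EDGES = (("1", "3"), ("1", "4"), ("2", "1"), ("4", "5"))


@dataclass(frozen=True)
class RegionSeriesSet:
    """Labeled multivariate time series, one row per region/channel.

    Attributes
    ----------
    labels : tuple of str
        Unique region names, in row order.
    data : ndarray, shape (n_regions, n_samples)
        The signals; must be finite.
    sfreq : float or None
        Sampling frequency in Hz, if known.
    """

    labels: tuple
    data: np.ndarray
    sfreq: float | None = None

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (regions x samples) array")
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {data.shape[0]} rows"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(data)):
            raise ValueError("series contain NaN or Inf")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "data", data)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.labels))


@dataclass(frozen=True)
class GroundTruthGraph:
    """Boolean directed adjacency over labeled nodes; entry (i, j) means i -> j."""

    labels: tuple
    adjacency: np.ndarray

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        adj = np.asarray(self.adjacency, dtype=bool)
        n = len(labels)
        if adj.shape != (n, n):
            raise ValueError("adjacency must be square with one row per label")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def from_edges(cls, labels, edges) -> "GroundTruthGraph":
        labels = tuple(str(l) for l in labels)
        idx = {l: i for i, l in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=bool)
        for src, dst in edges:
            adj[idx[str(src)], idx[str(dst)]] = True
        return cls(labels, adj)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edges(self):
        """Ordered (source, target) label pairs of present edges."""
        srcs, dsts = np.nonzero(self.adjacency)
        return [(self.labels[i], self.labels[j]) for i, j in zip(srcs, dsts)]


@dataclass(frozen=True)
class CoupledMapConfig:
    """Parameters of the five coupled quadratic maps.

    ``e`` is the coupling strength, ``a`` the quadratic map parameter and ``s``
    the standard deviation multiplying the unit-variance Gaussian innovations.
    ``n_transient`` initial samples are simulated and discarded so the returned
    segment is on the attractor.
    """

    e: float = 0.2
    a: float = 1.8
    s: float = 0.02
    n_samples: int = 1000
    n_transient: int = 1000
    seed: int | None = None
    initial_state: np.ndarray | None = None
    divergence_bound: float = 10.0
    max_restarts: int = 100

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.s < 0:
            raise ValueError("noise scale s must be >= 0")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("coupling e must lie in [0, 1]")
        if self.initial_state is not None:
            x0 = np.asarray(self.initial_state, dtype=float)
            if x0.shape != (5,):
                raise ValueError("initial_state must be a 5-vector")
            object.__setattr__(self, "initial_state", x0)


def _coupled_map_coupling_matrix(e: float) -> np.ndarray:
    """Per-node mixing weights of the benchmark: row i -> weight of f(x_j) in x_i."""
    C = np.zeros((5, 5))
    # map 2 is autonomous; maps 1, 3, 4 receive from their driver; 5 from 4
    C[0, 0], C[0, 1] = 1 - e, e      # 2 -> 1
    C[1, 1] = 1.0
    C[2, 2], C[2, 0] = 1 - e, e      # 1 -> 3
    C[3, 3], C[3, 0] = 1 - e, e      # 1 -> 4
    C[4, 4], C[4, 3] = 1 - e, e      # 4 -> 5
    return C


class DivergenceError(RuntimeError):
    """Trajectory left the admissible region too many times."""


def _iterate_maps(C, a, s, x0, n_total, bound, rng):
    """Run x(t) = C f(x(t-1)) + s tau(t) with f(x) = 1 - a x^2; None on divergence."""
    n_nodes = C.shape[0]
    out = np.empty((n_nodes, n_total))
    x = np.asarray(x0, dtype=float).copy()
    noise = rng.standard_normal((n_nodes, n_total)) if s > 0 else None
    for t in range(n_total):
        x = C @ (1.0 - a * x * x)
        if noise is not None:
            x = x + s * noise[:, t]
        if np.any(np.abs(x) > bound):
            return None
        out[:, t] = x
    return out


def simulate_coupled_maps(config: CoupledMapConfig | None = None):
    """Simulate the five-map benchmark system.

    Five first-order quadratic autoregressive maps x_i(t) = (1-e)(1 - a x_i(t-1)^2)
    + e (1 - a x_driver(t-1)^2) + s tau_i(t) with unit-variance Gaussian tau, wired
    so the true directed influences are 1->3, 1->4, 2->1 and 4->5 (map 2 is
    autonomous).  A transient is discarded; diverging trajectories (any |x|
    exceeding ``divergence_bound``) restart from a fresh random initial state
    drawn from a new RNG substream.

    Returns
    -------
    (RegionSeriesSet, GroundTruthGraph)
        ``n_samples`` post-transient samples of the five maps, and the fixed
        four-edge truth graph.
    """
    config = config or CoupledMapConfig()
    labels = ("1", "2", "3", "4", "5")
    truth = GroundTruthGraph.from_edges(labels, COUPLED_MAP_EDGES)
    C = _coupled_map_coupling_matrix(config.e)
    n_total = config.n_transient + config.n_samples

    ss = np.random.SeedSequence(config.seed)
    restarts = 0
    for attempt, child in enumerate(ss.spawn(config.max_restarts + 1)):
        rng = np.random.default_rng(child)
        if config.initial_state is not None and attempt == 0:
            x0 = config.initial_state
        else:
            x0 = rng.uniform(-0.5, 0.5, size=5)
        traj = _iterate_maps(C, config.a, config.s, x0, n_total,
                             config.divergence_bound, rng)
        if traj is not None:
            if restarts:
                logger.info("simulate_coupled_maps: %d divergent restart(s)", restarts)
            data = traj[:, config.n_transient:]
            return RegionSeriesSet(labels, data), truth
        restarts += 1
    raise DivergenceError(
        f"trajectory diverged in {restarts} consecutive attempts"
    )


def simulate_region_network(
    graph: GroundTruthGraph,
    coupling: float = 0.2,
    noise: float = 0.02,
    n_samples: int = 1000,
    n_transient: int = 1000,
    seed: int | None = None,
    a: float = 1.8,
    divergence_bound: float = 10.0,
    max_restarts: int = 100,
) -> RegionSeriesSet:
    """Stationary region-level series whose directed dependencies follow ``graph``.

    Generalizes the benchmark's functional form to an arbitrary topology: node i
    evolves as a convex mixture of the quadratic map applied to itself and to
    its parents, x_i(t) = (1-e_i)(1 - a x_i^2) + (e_i / k_i) sum_parents (1 - a x_p^2)
    + noise, where e_i = ``coupling`` if node i has parents (split evenly among
    the k_i parents) and 0 otherwise.  Each weight row sums to one, which keeps
    the noise-free dynamics in the map's invariant interval and the system
    stable for any coupling in [0, 1).

    Raises
    ------
    ValueError
        If coupling is outside [0, 1) (the offending value is reported).
    DivergenceError
        If trajectories repeatedly escape ``divergence_bound``.
    """
    if not 0.0 <= coupling < 1.0:
        raise ValueError(f"unstable configuration: coupling {coupling} not in [0, 1)")
    n = graph.n_nodes
    A = graph.adjacency
    C = np.zeros((n, n))
    for j in range(n):
        parents = np.nonzero(A[:, j])[0]
        if parents.size:
            C[j, j] = 1.0 - coupling
            C[j, parents] = coupling / parents.size
        else:
            C[j, j] = 1.0

    n_total = n_transient + n_samples
    ss = np.random.SeedSequence(seed)
    restarts = 0
    for child in ss.spawn(max_restarts + 1):
        rng = np.random.default_rng(child)
        x0 = rng.uniform(-0.5, 0.5, size=n)
        traj = _iterate_maps(C, a, noise, x0, n_total, divergence_bound, rng)
        if traj is not None:
            if restarts:
                logger.info("simulate_region_network: %d divergent restart(s)", restarts)
            return RegionSeriesSet(graph.labels, traj[:, n_transient:])
        restarts += 1
    raise DivergenceError(
        f"unstable configuration: diverged in {restarts} attempts at coupling {coupling}"
    )


#: Synthetic per-region channel counts for a 275-channel whole-head layout.
#: The true sensor-to-region assignment of the CTF system is not distributed
#: with this package; these counts are a plausible stand-in summing to 275.
_SYNTHETIC_REGION_COUNTS = {
    "LF": 22, "ZF": 20, "RF": 22, "LC": 18, "ZC": 16, "RC": 18,
    "LT": 24, "RT": 24, "LP": 19, "ZP": 17, "RP": 19,
    "LO": 19, "ZO": 18, "RO": 19,
}


def synthetic_channel_region_mapping() -> pd.DataFrame:
    """Synthetic 275-channel -> 14-region mapping table (columns channel, region).

    A stand-in for a real sensor layout: channels ch001…ch275 are assigned to
    the 14 region labels in blocks whose sizes sum to 275.  Use it to exercise
    :func:`average_channels_to_regions` or as a template for a real mapping.
    """
    rows = []
    k = 0
    for region in MEG_REGION_LABELS:
        for _ in range(_SYNTHETIC_REGION_COUNTS[region]):
            k += 1
            rows.append((f"ch{k:03d}", region))
    return pd.DataFrame(rows, columns=["channel", "region"])


def average_channels_to_regions(
    channels: np.ndarray,
    channel_labels,
    mapping: "pd.DataFrame | dict",
    unmapped: str = "error",
) -> RegionSeriesSet:
    """Average raw channel rows into one representative series per region.

    Parameters
    ----------
    channels : ndarray, shape (n_channels, n_samples)
    channel_labels : sequence of str
        Row labels of ``channels``.
    mapping : DataFrame with columns (channel, region), or dict channel -> region
        Region order in the output follows first appearance in the mapping.
    unmapped : {"error", "ignore"}
        Policy for channels present in the matrix but absent from the mapping.
    """
    channels = np.asarray(channels, dtype=float)
    channel_labels = [str(c) for c in channel_labels]
    if channels.ndim != 2 or channels.shape[0] != len(channel_labels):
        raise ValueError("channels must be (n_channels, n_samples) with one label per row")
    if isinstance(mapping, dict):
        pairs = [(str(k), str(v)) for k, v in mapping.items()]
    else:
        df = pd.DataFrame(mapping)
        pairs = [(str(c), str(r)) for c, r in zip(df.iloc[:, 0], df.iloc[:, 1])]

    mapped = dict(pairs)
    for ch in mapped:
        if ch not in channel_labels:
            raise ValueError(f"mapping references unknown channel {ch!r}")
    missing = [c for c in channel_labels if c not in mapped]
    if missing and unmapped == "error":
        raise ValueError(
            f"{len(missing)} channel(s) not covered by the mapping "
            f"(first: {missing[0]!r}); pass unmapped='ignore' to drop them"
        )

    region_order: list[str] = []
    members: dict[str, list[int]] = {}
    row_of = {c: i for i, c in enumerate(channel_labels)}
    for ch, region in pairs:
        if region not in members:
            region_order.append(region)
            members[region] = []
        members[region].append(row_of[ch])
    for region, rows in members.items():
        if not rows:
            raise ValueError(f"region {region!r} has no channels")

    data = np.vstack([channels[members[r]].mean(axis=0) for r in region_order])
    return RegionSeriesSet(tuple(region_order), data)
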