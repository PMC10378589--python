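"""Node and whole-network statistics of directed weighted graphs.

For a nonnegative weight matrix W with zero diagonal, each node has an
in-strength (column sum), out-strength (row sum) and total strength; dividing
by the grand total w_sum turns strengths into probability distributions over
nodes.  Two whole-network summaries are computed from those distributions:

* nonequilibrium — a subtraction-based probabilistic difference between a
  node's in- and out-probabilities, YS = hi (hi − lo)/(hi + lo) with
  (hi, lo) the ordered pair, summed over nodes for the network value.  It is
  zero exactly when every node sends as much as it receives, and unlike
  ratio-based divergences it stays defined when one of the two strengths
  vanishes (the limit is YS = hi).
* Shannon entropy of the in- and out-strength distributions (natural log),
  bounded by ln R and maximal for uniform strengths.

All three families are invariant under global rescaling of W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightedDigraph",
    "NodeStrengths",
    "NonequilibriumResult",
    "EntropyResult",
    "strengths",
    "ys_local",
    "nonequilibrium",
    "strength_entropies",
    "metrics_table",
]


@dataclass(frozen=True)
class WeightedDigraph:
    """Nonnegative directed weight matrix with labels; W[i, j] weights i -> j."""

    labels: tuple
    W: np.ndarray

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        W = np.asarray(self.W, dtype=float)
        n = len(labels)
        if W.shape != (n, n):
            raise ValueError("W must be square, one row per label")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diagonal(W) != 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "W", W)

    @classmethod
    def from_causality_matrix(cls, cm) -> "WeightedDigraph":
        return cls(cm.labels, cm.W)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j and self.W[i, j] > 0:
                    g.add_edge(a, b, weight=float(self.W[i, j]))
        return g


@dataclass(frozen=True)
class NodeStrengths:
    labels: tuple
    w_in: np.ndarray
    w_out: np.ndarray
    w_total: np.ndarray
    w_sum: float

    @property
    def p_in(self) -> np.ndarray:
        if self.w_sum <= 0:
            raise ValueError("empty network: w_sum = 0")
        return self.w_in / self.w_sum

    @property
    def p_out(self) -> np.ndarray:
        if self.w_sum <= 0:
            raise ValueError("empty network: w_sum = 0")
        return self.w_out / self.w_sum


@dataclass(frozen=True)
class NonequilibriumResult:
    labels: tuple
    ys_local: np.ndarray
    ys_network: float


@dataclass(frozen=True)
class EntropyResult:
    entropy_in: float
    entropy_out: float


def strengths(graph: WeightedDigraph) -> NodeStrengths:
    """In-, out- and total connectivity strength per node plus the grand total."""
    W = graph.W
    w_in = W.sum(axis=0)
    w_out = W.sum(axis=1)
    return NodeStrengths(graph.labels, w_in, w_out, w_in + w_out, float(W.sum()))


def ys_local(p_in: float, p_out: float) -> float:
    """Probabilistic in/out difference hi (hi - lo)/(hi + lo) of one node.

    The larger probability plays the role of hi; if both vanish the node is
    balanced (0); if only the smaller vanishes the value is hi.
    """
    if p_in < 0 or p_out < 0:
        raise ValueError("probabilities must be nonnegative")
    hi, lo = (p_in, p_out) if p_in >= p_out else (p_out, p_in)
    if hi == 0.0:
        return 0.0
    return hi * (hi - lo) / (hi + lo)


def nonequilibrium(graph: WeightedDigraph) -> NonequilibriumResult:
    """Node-level and whole-network nonequilibrium of the strength distributions."""
    st = strengths(graph)
    if st.w_sum <= 0:
        raise ValueError("empty network: w_sum = 0")
    ys = np.array([ys_local(pi, po) for pi, po in zip(st.p_in, st.p_out)])
    return NonequilibriumResult(graph.labels, ys, float(ys.sum()))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def strength_entropies(graph: WeightedDigraph) -> EntropyResult:
    """Shannon entropies (nats) of the in- and out-strength distributions."""
    st = strengths(graph)
    if st.w_sum <= 0:
        raise ValueError("empty network: w_sum = 0")
    return EntropyResult(_entropy(st.p_in), _entropy(st.p_out))


def metrics_table(graph: WeightedDigraph) -> pd.DataFrame:
    """Per-node metrics table with a trailing network-level row.

    Columns: node, w_in, w_out, w_total, p_in, p_out, ys_local; the final row
    labelled ``<network>`` carries w_sum, YS_W and the two entropies.
    """
    st = strengths(graph)
    ne = nonequilibrium(graph)
    en = strength_entropies(graph)
    df = pd.DataFrame({
        "node": list(graph.labels),
        "w_in": st.w_in,
        "w_out": st.w_out,
        "w_total": st.w_total,
        "p_in": st.p_in,
        "p_out": st.p_out,
        "ys_local": ne.ys_local,
    })
    net = pd.DataFrame([{
        "node": "<network>",
        "w_in": st.w_sum,
        "w_out": st.w_sum,
        "w_total": 2 * st.w_sum,
        "p_in": np.nan,
        "p_out": np.nan,
        "ys_local": ne.ys_network,
    }])
    out = pd.concat([df, net], ignore_index=True)
    out.attrs.update(
        w_sum=st.w_sum, ys_network=ne.ys_network,
        entropy_in=en.entropy_in, entropy_out=en.entropy_out,
    )
    return out
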