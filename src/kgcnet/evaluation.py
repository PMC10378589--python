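"""Detection scoring against ground truth and the coupled-map benchmark.

An inferred causality matrix is binarized (an edge is detected iff its
FDR-filtered index is strictly positive — the filter itself is the
significance decision), compared with a known directed graph over the ordered
off-diagonal node pairs, and summarized by sensitivity, specificity and the
Matthews correlation coefficient.  The benchmark repeats this over many
independent simulations of the five-map system for each requested method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CoupledMapConfig, GroundTruthGraph, simulate_coupled_maps
from .kgc import CausalityMatrix, GCConfig, causality_matrix

__all__ = [
    "ConfusionCounts",
    "MethodPerformance",
    "BenchmarkConfig",
    "detect_edges",
    "confusion",
    "performance",
    "run_benchmark",
    "benchmark_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-detection confusion counts over ordered node pairs (diagonal excluded)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MethodPerformance:
    """Per-run sensitivity/specificity/Mcc with mean and sd across runs.

    Values are reported as fractions in [0, 1] (Mcc can be negative in
    principle but is nonnegative for any reasonable detector here).
    """

    method: str
    sensitivity: np.ndarray
    specificity: np.ndarray
    mcc: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.sensitivity)

    def summary(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "mcc"):
            v = getattr(self, name)
            out[name] = float(np.mean(v))
            out[name + "_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        out["n_runs"] = self.n_runs
        return out


def detect_edges(matrix: CausalityMatrix) -> GroundTruthGraph:
    """Binarize a causality matrix: edge present iff its index is strictly > 0."""
    return GroundTruthGraph(matrix.labels, matrix.W > 0)


def confusion(detected: GroundTruthGraph, truth: GroundTruthGraph) -> ConfusionCounts:
    """Confusion counts of detected vs true edges over ordered off-diagonal pairs."""
    if detected.labels != truth.labels:
        raise ValueError("node labels of detected and truth graphs differ")
    n = truth.n_nodes
    off = ~np.eye(n, dtype=bool)
    d = detected.adjacency[off]
    t = truth.adjacency[off]
    return ConfusionCounts(
        tp=int(np.sum(d & t)),
        tn=int(np.sum(~d & ~t)),
        fp=int(np.sum(d & ~t)),
        fn=int(np.sum(~d & t)),
    )


def performance(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity and Matthews correlation of one confusion table.

    Reported as fractions.  A zero factor in the Mcc denominator yields
    Mcc = 0 by convention; sensitivity requires at least one true edge.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no true edges")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"sensitivity": sens, "specificity": spec, "mcc": mcc}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Settings of the repeated five-map detection benchmark."""

    n_runs: int = 200
    map_config: CoupledMapConfig = field(default_factory=CoupledMapConfig)
    gc_config: GCConfig | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


_METHOD_CONFIGS = {
    "blgc": lambda base: GCConfig(m=base.m, kernel="linear", fdr_q=base.fdr_q,
                                  eig_tol=base.eig_tol, center_gram=base.center_gram,
                                  standardize=base.standardize),
    "bkgc": lambda base: base,
    "mkgc": lambda base: base,
}


def run_benchmark(config: BenchmarkConfig | None = None,
                  methods=("blgc", "bkgc", "mkgc")) -> dict:
    """Score each method's edge detection over repeated five-map simulations.

    Every run simulates a fresh realization of the coupled-map system from a
    per-run substream of the master seed, computes the causality matrix for
    each method, binarizes it and scores it against the four true edges.
    Returns ``{method: MethodPerformance}``; fully reproducible from the seed.
    """
    config = config or BenchmarkConfig()
    base_gc = config.gc_config or GCConfig()
    for m in methods:
        if m not in _METHOD_CONFIGS:
            raise ValueError(f"unknown method {m!r}")

    per_method = {m: {"sensitivity": [], "specificity": [], "mcc": []} for m in methods}
    run_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    for run, run_seed in enumerate(run_seeds):
        map_cfg = CoupledMapConfig(
            e=config.map_config.e, a=config.map_config.a, s=config.map_config.s,
            n_samples=config.map_config.n_samples,
            n_transient=config.map_config.n_transient,
            seed=int(run_seed),
        )
        try:
            series, truth = simulate_coupled_maps(map_cfg)
            for m in methods:
                cm = causality_matrix(series, m, _METHOD_CONFIGS[m](base_gc))
                perf = performance(confusion(detect_edges(cm), truth))
                for k, v in perf.items():
                    per_method[m][k].append(v)
        except Exception as exc:
            raise RuntimeError(f"benchmark run {run} failed: {exc}") from exc

    return {
        m: MethodPerformance(
            m,
            np.array(per_method[m]["sensitivity"]),
            np.array(per_method[m]["specificity"]),
            np.array(per_method[m]["mcc"]),
        )
        for m in methods
    }


def benchmark_table(results: dict) -> pd.DataFrame:
    """Summarize benchmark results as a table of mean ± sd per method."""
    rows = []
    for method, perf in results.items():
        s = perf.summary()
        rows.append({
            "method": method,
            "sensitivity": s["sensitivity"], "sensitivity_sd": s["sensitivity_sd"],
            "specificity": s["specificity"], "specificity_sd": s["specificity_sd"],
            "mcc": s["mcc"], "mcc_sd": s["mcc_sd"],
            "n_runs": s["n_runs"],
        })
    return pd.DataFrame(rows)
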