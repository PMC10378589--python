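"""Two-group cohort analysis on synthetic region-level series.

Builds two cohorts of six-region subjects whose coupling graphs share edge
A->B but differ in one edge each (C->D in the first group, E->F in the
second), runs the per-subject network inference with surrogate pruning, and
compares every directed edge across groups with the Mann-Whitney U test.
The differential connectivity graph should recover the constructed
differences with small p-values.
"""

from kgcnet import (
    GCConfig, GroundTruthGraph, PipelineConfig, SubjectRecord,
    run_pipeline, simulate_region_network,
)

LABELS = ("A", "B", "C", "D", "E", "F")
graph_a = GroundTruthGraph.from_edges(LABELS, [("A", "B"), ("C", "D")])
graph_b = GroundTruthGraph.from_edges(LABELS, [("A", "B"), ("E", "F")])

subjects = []
for group, graph, offset in (("G1", graph_a, 0), ("G2", graph_b, 500)):
    for k in range(6):
        series = simulate_region_network(graph, coupling=0.25, noise=0.02,
                                         n_samples=600, seed=offset + k)
        subjects.append(SubjectRecord(f"{group}_{k}", group, series=series))

bundle = run_pipeline(PipelineConfig(
    subjects=subjects, gc=GCConfig(m=1, p=2), order=1,
    n_surrogates=25, prune=True, seed=42))

diff = bundle["differential_graph"]
print(diff[["source", "target", "p_value", "mean_a", "mean_b"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nedges constructed to differ: C->D (group 1 only), E->F (group 2 only);"
      "\nmean_a / mean_b are the group-mean edge weights entering the test.")
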