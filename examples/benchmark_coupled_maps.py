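"""Detection benchmark on the five coupled quadratic maps.

Simulates the five-map system (four wired couplings: 1->3, 1->4, 2->1, 4->5)
twenty times, infers the directed network with each Granger-causality method,
and scores the detected edges against the wired graph.  Sensitivity is the
fraction of wired couplings detected, specificity the fraction of absent
ordered pairs left undetected, and Mcc balances both.  The multivariate
kernel method should dominate: it conditions on the remaining maps and so
ignores influence that is merely mediated.
"""

from kgcnet import BenchmarkConfig, benchmark_table, run_benchmark

results = run_benchmark(BenchmarkConfig(n_runs=20, seed=7))
table = benchmark_table(results)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nmkgc keeps specificity near 1 because conditioning on the other maps"
    "\nremoves mediated influence; the bivariate kernel method (bkgc) flags"
    "\nmediated pairs as causal and pays for it in specificity."
)
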