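"""Direct versus mediated influence on a single simulated run.

Map 2 drives map 1, and map 1 drives map 3; there is no direct coupling
2->3.  A bivariate index sees the chain 2->1->3 as causality 2->3, while the
multivariate index conditions on map 1 and assigns the mediated pair zero.
"""

from kgcnet import (
    CoupledMapConfig, GCConfig, bkgc, mkgc, simulate_coupled_maps,
)

series, truth = simulate_coupled_maps(CoupledMapConfig(seed=11))
cfg = GCConfig(m=1, p=2)
data = series.data

pairs = {"2->1 (direct)": (1, 0), "2->3 (mediated)": (1, 2),
         "4->5 (direct)": (3, 4)}
print(f"{'pair':18s} {'bivariate':>10s} {'multivariate':>13s}")
for name, (i, j) in pairs.items():
    bi = bkgc(data[i], data[j], cfg).value
    multi = mkgc(series, i, j, cfg).value
    print(f"{name:18s} {bi:10.4f} {multi:13.4f}")
print(
    "\nBoth methods score the direct couplings; only the multivariate index"
    "\nreturns exactly zero for the mediated pair."
)
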