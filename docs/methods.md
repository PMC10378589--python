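# Methods

## Model and estimator

The causality index for a directed pair (a → b) compares two kernel
regressions of the target vector **x** — the future samples of series b,
centered and scaled to unit norm over the N = T − m realizations — on lag
vectors of order m. The restricted design stacks the lag vectors of every
observed series except a (in the bivariate variants, only b's own past); the
full design adds a's lags. Predictor lag components are centered across
realizations in the embedding and, by default, scaled to unit variance
before kernel evaluation (a conditioning measure; for polynomial kernels the
spanned feature space, and hence the raw index, is unchanged by per-component
scaling).

Regression is performed geometrically through Gram matrices of the
inhomogeneous polynomial kernel K_p(u, v) = (1 + u·v)^p. With P the
orthogonal projector onto range(K) of the restricted Gram matrix, the
restricted prediction is x̃ = Px and the residual y = x − Px. The additional
feature directions contributed by the driver span range(K̃) with
K̃ = (I − P) K′ (I − P), and the raw index

δ = ‖P⊥y‖² / (1 − x̃ᵀx̃)

is a variance-ratio in [0, 1]; on linear kernels it equals
1 − RSS_full / RSS_restricted of explicit least squares (tested to 1e−8).
Overfitting control: every eigenvector tᵢ of K̃ with nonvanishing eigenvalue
is correlated with y (Pearson rᵢ), transformed by Fisher's
z = atanh(r)·√(N − 3), two-sided normal p-values are corrected by
Benjamini–Hochberg at level q, and the filtered index δF sums rᵢ² over
survivors. δF = 0 (no surviving eigenvector) is the no-causality decision.

### Computation

The IP kernel has a finite feature space: (1 + u·v)^p expands over monomials
of total degree ≤ p with multinomial weights, so the package computes all
projections from explicit weighted-monomial feature matrices and thin SVDs.
For the benchmark's five series at m = 1, p = 2 this means 21-dimensional
feature spaces instead of 1000×1000 eigendecompositions; the spanned
subspaces are mathematically identical (the feature map reproduces the
kernel to machine precision, tested), and the dense K, K′, K̃ and P remain
available on `GramPair` for verification. A full three-method, 200-run
benchmark takes ~20 s on one CPU.

## Parameters

- **m** (lag order, default 1): selected on request by BIC over a *linear*
  VAR fit (1 … max_m) — the kernel model has no closed-form likelihood, so
  the linear surrogate model is the order-selection vehicle. On the
  benchmark system BIC returns 1 essentially always.
- **p** (kernel order, default 2): degree of nonlinearity; p = 1 is linear
  GC exactly (identity tested to 1e−10). Capped at 5 with a warning because
  the feature dimension grows combinatorially.
- **q** (`fdr_q`, default 0.05): FDR level of the eigenvector filter. Under
  a true null pair the BH procedure fires with probability ≈ q (it controls
  family-wise error at q under the global null), so on a system with many
  absent edges the expected specificity of δF-based detection is ≈ 1 − q.
  This ceiling is inherent to the filter, not a defect; a stricter q trades
  false edges for power.
- **eig_tol** (default 1e−8, relative to the largest eigenvalue): numerical
  threshold for "nonvanishing" eigenvalues — a rank cutoff, not exact zero.
- **center_gram** (default on): double-centers Gram matrices (equivalently,
  centers feature columns), making the kernel features zero-mean as the
  projection formulation assumes; with centering on, the p = 1 kernel and
  the plain linear Gram give identical indices.
- **Surrogates** (default 200, α = 0.05, source mode): IAAFT iterations cap
  at 100 with convergence on a stable rank permutation; the final step is
  always amplitude adjustment, so the surrogate's value multiset is exactly
  the original's.

## Surrogate testing choices

What to surrogate: replacing only the *source* series destroys directed
coupling into the target while preserving the target's autostructure — the
sharpest null for a directed edge; replacing all series is available
(`mode="all"`). The statistic compared by rank against the null ensemble is
the *unfiltered* δ rather than δF: δ is continuous, so the rank p-value
(1 + #{surrogate ≥ original})/(n + 1) is exactly distribution-free, whereas
δF's atom at zero produces ties that make the rank test conservative (the
filtered weight is still what the pruned matrix carries — pruning only ever
zeroes entries). The φ statistic (original minus surrogate mean, in surrogate
standard deviations) is reported descriptively; the rank p is the operative
test. No multiplicity correction is applied across edges at the pruning
stage, and none across edges or regions in the group comparison; a
Benjamini–Hochberg option can be applied downstream by the user on the
reported p-value tables.

## Synthetic data

`simulate_coupled_maps` implements five noisy first-order quadratic maps
x_i(t) = (1−e)(1 − a·x_i²(t−1)) + e(1 − a·x_drv²(t−1)) + s·τ_i(t) with
defaults e = 0.2, a = 1.8, s = 0.02, N = 1000 and wired couplings 1→3, 1→4,
2→1, 4→5 (map 2 autonomous). Initial states are drawn uniformly from
(−0.5, 0.5) and a 1000-sample transient is discarded so segments sit on the
attractor. The quadratic map's trapping interval is |x| ≲ 1.073; with
s = 0.02 escapes are rare, and any trajectory exceeding |x| = 10 triggers a
restart from a fresh RNG substream (counted and logged) rather than
clipping, preserving stationarity. A single master seed derives all per-run
substreams, so multi-run benchmarks are exactly reproducible.

`simulate_region_network` generalizes the same dynamics to an arbitrary
directed graph (each node a convex mixture of its own map and its parents'
maps, coupling split evenly among parents), producing stationary,
weakly coupled nonlinear series with a known ground-truth graph — a
stand-in for region-averaged resting-state recordings. What it does *not*
emulate: 1/f-like spectra, volume conduction / field spread between sensors,
nonstationarity, measurement noise correlation, or realistic amplitude
distributions. Passing tests on these series therefore demonstrate
correctness of the inference machinery and its null calibration, not
performance on real neurophysiological data. The packaged 275-channel →
14-region mapping (`synthetic_channel_region_mapping`) is likewise a
synthetic stand-in: block assignment with plausible per-region counts, not a
real sensor layout.

## Numerical and design notes

- Degenerate inputs: constant target series raise (`degenerate target`);
  when the restricted model explains the target to within 1e−12 the index is
  defined as 0 with a warning.
- Degenerate spectra: within an eigenspace of K̃ the FDR decision can depend
  on the solver's basis choice; δF is rotation-invariant only when a whole
  eigenspace passes or fails together. Eigenvectors are taken as returned by
  the SVD; a regression test pins the behavior on a fixed matrix family.
- Mcc with a zero denominator factor is defined as 0. Sensitivity,
  specificity and Mcc are reported as fractions in [0, 1] rather than
  percentages.
- Benchmark aggregation is mean ± sd of per-run metrics (pooling counts
  across runs is available but not the default).
- Mann–Whitney comparisons are two-sided with midranks; exact enumeration
  for pooled n ≤ 12 without ties, tie-corrected normal approximation
  otherwise (scipy). Group metrics are computed per subject and compared
  across subjects.
- The nonequilibrium node index uses the ordered pair (hi ≥ lo) of in/out
  probabilities, YS = hi(hi − lo)/(hi + lo), with YS = hi when the smaller
  probability is 0 (the formula's limit) and 0 when both vanish — the
  subtraction form stays defined where ratio-based divergences do not.
  Strength entropies use the natural logarithm.

## Problem sizes

The test suite uses 300 runs for the mediated-pair structure check, 40 for
the full three-method benchmark comparison, 400 repetitions for surrogate
null calibration, and three 16-subject cohort replicates for the pipeline
recovery property; `scripts/acceptance.py` runs the full 200-run benchmark.
Empirical-rate thresholds in tests were frozen from larger calibration runs
(noted inline where they apply).

## Known limitations

- With the default q = 0.05 filter, specificity on null-heavy systems
  plateaus near 1 − q per pair (see above); reported specificities in the
  kernel-GC literature that exceed this imply stricter (often unstated)
  corrections.
- On nearly deterministic chaotic systems, bivariate indices can genuinely
  detect weak *reverse* influence (the driven series carries information
  about the driver's past states), depressing bivariate specificity; this is
  a property of bivariate GC on such systems, not an estimator artifact
  (the detected reverse index stabilizes, rather than vanishes, as N grows).
- No frequency-domain GC, no Gaussian/RBF kernels, no conditional/partial
  linear GC variants, and no raw-recording preprocessing (inputs are assumed
  artifact-free and filtered).
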