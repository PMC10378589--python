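"""Kernel Granger causality via Gram-matrix projections.

The causality index compares a restricted regression of a target signal's
future on past values (its own past, and — in the multivariate case — the past
of every other observed signal except the candidate driver) with a full
regression that adds the candidate driver's past.  Both regressions are kernel
regressions in the reproducing-kernel Hilbert space of the inhomogeneous
polynomial (IP) kernel K_p(u, v) = (1 + u·v)^p; the linear case is p = 1 with
the plain inner product.

Geometrically, with Gram matrices K (restricted) and K' (full) over the N
realizations, the restricted model predicts x̃ = Px where P projects onto the
range of K.  The extra explanatory directions contributed by the driver span
the range of K̃ = K' − PK' − K'P + PK'P, i.e. the orthogonal complement of
range(K) inside range(K').  The raw index is

    δ = ‖P⊥ y‖² / (1 − x̃ᵀx̃),     y = x − Px,

a fraction of residual variance explained, equal to Σ r_i² over the Pearson
correlations r_i between y and the eigenvectors t_i of K̃ with nonvanishing
eigenvalue.  To guard against overfitting, each r_i is tested via Fisher's
r-to-z transform with Benjamini–Hochberg FDR control, and the filtered index
δF sums r_i² over the survivors only; δF = 0 means no detected causality.

Because the IP kernel has a finite-dimensional feature space, all projections
are computed here from explicit multinomial-weighted polynomial feature maps
and thin SVDs rather than dense N×N eigendecompositions; the spanned spaces
are identical and the dense matrices remain available on :class:`GramPair`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import RegionSeriesSet

__all__ = [
    "GCConfig",
    "LaggedDesign",
    "GramPair",
    "FdrSelection",
    "CausalityIndex",
    "CausalityMatrix",
    "embed",
    "ip_kernel",
    "polynomial_features",
    "build_gram_pair",
    "fdr_filtered_index",
    "blgc",
    "bkgc",
    "mkgc",
    "causality_matrix",
    "select_order_bic",
]

MAX_KERNEL_ORDER = 5


class DegenerateTargetError(ValueError):
    """The target series has (numerically) zero variance."""


@dataclass(frozen=True)
class GCConfig:
    """Settings of a Granger-causality computation.

    Parameters
    ----------
    m : int
        Autoregression order (number of lags), >= 1.
    kernel : {"linear", "inhomogeneous_polynomial"}
    p : int
        IP kernel order (ignored for the linear kernel); capped at 5 because
        the polynomial feature dimension grows combinatorially.
    fdr_q : float
        Benjamini–Hochberg level for eigenvector selection.
    eig_tol : float
        Relative threshold (w.r.t. the largest eigenvalue) below which Gram
        eigenvalues count as vanishing; this is a numerical-rank cutoff.
    center_gram : bool
        Center Gram matrices in feature space (double centering).
    standardize : bool
        Scale each lag component to unit variance before kernel evaluation.
    """

    m: int = 1
    kernel: str = "inhomogeneous_polynomial"
    p: int = 2
    fdr_q: float = 0.05
    eig_tol: float = 1e-8
    center_gram: bool = True
    standardize: bool = True

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("order m must be >= 1")
        if self.kernel not in ("linear", "inhomogeneous_polynomial"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.p < 1:
            raise ValueError("kernel order p must be >= 1")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.p > MAX_KERNEL_ORDER:
            warnings.warn(
                f"IP kernel order p={self.p} capped at {MAX_KERNEL_ORDER}",
                RuntimeWarning,
            )
            object.__setattr__(self, "p", MAX_KERNEL_ORDER)


@dataclass(frozen=True)
class LaggedDesign:
    """Lag-vector predictors and normalized target over N realizations.

    ``predictors_restricted`` and ``predictors_full`` hold lag vectors as
    columns (components x N); the target is centered with unit Euclidean norm.
    """

    predictors_restricted: np.ndarray
    predictors_full: np.ndarray
    target: np.ndarray
    n_realizations: int = field(init=False)

    def __post_init__(self):
        pr = np.atleast_2d(np.asarray(self.predictors_restricted, dtype=float))
        pf = np.atleast_2d(np.asarray(self.predictors_full, dtype=float))
        x = np.asarray(self.target, dtype=float).ravel()
        n = x.size
        if pr.shape[1] != n or pf.shape[1] != n:
            raise ValueError("predictors and target disagree on N")
        if abs(x.mean()) > 1e-8 or abs(x @ x - 1.0) > 1e-8:
            raise ValueError("target must be centered with unit norm (use embed)")
        object.__setattr__(self, "predictors_restricted", pr)
        object.__setattr__(self, "predictors_full", pf)
        object.__setattr__(self, "target", x)
        object.__setattr__(self, "n_realizations", n)


def embed(series, m: int):
    """Delay-embed a scalar series into lag vectors and a normalized target.

    Returns ``(lags, target)`` where ``lags[:, i] = (s_i, …, s_{i+m-1})`` and
    the raw target is ``s_{i+m}``, for i = 0…N−1 with N = len(series) − m.
    Each lag component is centered across realizations; the target is centered
    and scaled to unit norm.
    """
    s = np.asarray(series, dtype=float).ravel()
    if m < 1:
        raise ValueError("m must be >= 1")
    if s.size <= m:
        raise ValueError(f"series of length {s.size} too short for m={m}")
    if not np.all(np.isfinite(s)):
        raise ValueError("series contains non-finite values")
    n = s.size - m
    lags = np.lib.stride_tricks.sliding_window_view(s, m)[:n].T.copy()
    target = s[m:].astype(float)
    lags -= lags.mean(axis=1, keepdims=True)
    target = target - target.mean()
    nrm = np.linalg.norm(target)
    scale = max(1.0, np.abs(s).max())
    if nrm <= 1e-12 * scale * math.sqrt(n):
        raise DegenerateTargetError("degenerate target: series is constant")
    return lags, target / nrm


def ip_kernel(u, v, p: int) -> float:
    """Inhomogeneous polynomial kernel (1 + u·v)^p."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("u and v must have equal dimension")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float((1.0 + u @ v) ** p)


def polynomial_features(L: np.ndarray, p: int) -> np.ndarray:
    """Exact finite feature map of the IP kernel.

    For lag matrix ``L`` (d x N) returns ``F`` (D x N) with
    ``F[:, i]·F[:, j] == (1 + L[:, i]·L[:, j])**p``: one row per monomial of
    total degree <= p, weighted by the square root of its multinomial
    coefficient in the expansion of (1 + u·v)^p.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    d, n = L.shape
    rows = []
    for total in range(p + 1):
        for combo in combinations_with_replacement(range(d), total):
            coef = math.factorial(p) // math.factorial(p - total)
            for c in np.bincount(np.array(combo, dtype=int), minlength=1) if combo else []:
                coef //= math.factorial(int(c))
            row = np.full(n, math.sqrt(coef))
            for idx in combo:
                row = row * L[idx]
            rows.append(row)
    return np.vstack(rows)


@dataclass(frozen=True)
class GramPair:
    """Restricted/full Gram matrices in factored (feature-space) form.

    Stores the feature matrices and orthonormal bases of the relevant ranges;
    the dense N×N objects — K, K', K̃ and the projector P onto range(K) — are
    reconstructed on demand, so small-scale checks can exercise the matrix
    identities while large-N computation stays in the thin factors.
    """

    features_restricted: np.ndarray   # d_r x N
    features_full: np.ndarray         # d_f x N
    basis_restricted: np.ndarray      # N x k_r, orthonormal columns spanning range(K)
    eigvals_restricted: np.ndarray
    basis_tilde: np.ndarray           # N x k_t, orthonormal columns spanning range(K̃)
    eigvals_tilde: np.ndarray

    @property
    def rank_K(self) -> int:
        return self.basis_restricted.shape[1]

    @property
    def K(self) -> np.ndarray:
        return self.features_restricted.T @ self.features_restricted

    @property
    def K_full(self) -> np.ndarray:
        return self.features_full.T @ self.features_full

    @property
    def P(self) -> np.ndarray:
        V = self.basis_restricted
        return V @ V.T

    @property
    def K_tilde(self) -> np.ndarray:
        V = self.basis_tilde
        return (V * self.eigvals_tilde) @ V.T


def _range_basis(F: np.ndarray, eig_tol: float):
    """Orthonormal basis of range(FᵀF) with eigenvalues above eig_tol·λ_max."""
    if F.size == 0:
        n = F.shape[1] if F.ndim == 2 else 0
        return np.empty((n, 0)), np.empty(0)
    # right singular vectors of F are eigenvectors of the Gram FᵀF
    _, s, Vt = np.linalg.svd(F, full_matrices=False)
    eig = s * s
    if eig.size == 0 or eig[0] <= 0.0:
        return np.empty((F.shape[1], 0)), np.empty(0)
    keep = eig > eig_tol * eig[0]
    return Vt[keep].T, eig[keep]


def _prepare_features(pred: np.ndarray, config: GCConfig) -> np.ndarray:
    X = pred - pred.mean(axis=1, keepdims=True)
    if config.standardize:
        sd = X.std(axis=1, keepdims=True)
        sd[sd < 1e-300] = 1.0
        X = X / sd
    if config.kernel == "linear":
        F = X
    else:
        F = polynomial_features(X, config.p)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError(
            "non-finite Gram features (overflow at high kernel order p?)"
        )
    if config.center_gram:
        F = F - F.mean(axis=1, keepdims=True)
    return F


def build_gram_pair(design: LaggedDesign, config: GCConfig) -> GramPair:
    """Build the restricted/full Gram pair and the bases of range(K), range(K̃)."""
    F_r = _prepare_features(design.predictors_restricted, config)
    F_f = _prepare_features(design.predictors_full, config)
    V_r, eig_r = _range_basis(F_r, config.eig_tol)
    # project the restricted range out of the full features: K̃ = GᵀG
    G = F_f - (F_f @ V_r) @ V_r.T
    V_t, eig_t = _range_basis(G, config.eig_tol)
    return GramPair(F_r, F_f, V_r, eig_r, V_t, eig_t)


@dataclass(frozen=True)
class FdrSelection:
    """Per-eigenvector test results of the Fisher/FDR filter."""

    eigenvectors: np.ndarray   # N x k
    eigenvalues: np.ndarray
    correlations: np.ndarray
    z_scores: np.ndarray
    p_values: np.ndarray
    passed: np.ndarray         # boolean mask


@dataclass(frozen=True)
class CausalityIndex:
    """Filtered causality index δF with diagnostics.

    ``value`` is δF (zero iff no eigenvector survived the FDR filter);
    ``delta`` is the unfiltered δ of the raw projection ratio.
    """

    value: float
    delta: float
    n_passed: int
    n_candidates: int
    selection: FdrSelection | None = None


def fdr_filtered_index(
    design: LaggedDesign, gram: GramPair, config: GCConfig,
    keep_selection: bool = False,
) -> CausalityIndex:
    """Compute δ and the FDR-filtered δF from a prebuilt Gram pair."""
    x = design.target
    n = design.n_realizations
    if n < 5:
        raise ValueError("need at least 5 realizations for the Fisher r-to-z test")
    V_r = gram.basis_restricted
    xt = V_r @ (V_r.T @ x)
    y = x - xt
    denom = 1.0 - xt @ xt
    if denom < 1e-12:
        warnings.warn(
            "target fully explained by the restricted model; index set to 0",
            RuntimeWarning,
        )
        return CausalityIndex(0.0, 0.0, 0, gram.basis_tilde.shape[1])

    T = gram.basis_tilde
    k = T.shape[1]
    if k == 0:
        return CausalityIndex(0.0, 0.0, 0, 0)

    proj = T.T @ y
    delta = float(np.clip(proj @ proj / denom, 0.0, 1.0))

    # Pearson correlation of y with each candidate eigenvector
    yc = y - y.mean()
    Tc = T - T.mean(axis=0, keepdims=True)
    y_nrm = np.linalg.norm(yc)
    t_nrm = np.linalg.norm(Tc, axis=0)
    safe = (t_nrm > 0) & (y_nrm > 0)
    r = np.zeros(k)
    r[safe] = (yc @ Tc[:, safe]) / (y_nrm * t_nrm[safe])
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0 + 1e-16, 1.0 - 1e-16))
    z *= math.sqrt(max(n - 3, 1))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    passed = multipletests(pvals, alpha=config.fdr_q, method="fdr_bh")[0]

    value = float(np.clip(np.sum(r[passed] ** 2), 0.0, 1.0))
    sel = None
    if keep_selection:
        sel = FdrSelection(T, gram.eigvals_tilde, r, z, pvals, passed)
    return CausalityIndex(value, delta, int(passed.sum()), k, sel)


def _pairwise_design(source, target, m: int) -> LaggedDesign:
    src = np.asarray(source, dtype=float).ravel()
    tgt = np.asarray(target, dtype=float).ravel()
    if src.size != tgt.size:
        raise ValueError("source and target must have equal length")
    lags_t, x = embed(tgt, m)
    lags_s, _ = embed(src, m)
    return LaggedDesign(lags_t, np.vstack([lags_t, lags_s]), x)


def blgc(source, target, config: GCConfig | None = None, **kw) -> CausalityIndex:
    """Bivariate linear Granger causality index source → target."""
    config = replace(config or GCConfig(), kernel="linear")
    design = _pairwise_design(source, target, config.m)
    return fdr_filtered_index(design, build_gram_pair(design, config), config, **kw)


def bkgc(source, target, config: GCConfig | None = None, **kw) -> CausalityIndex:
    """Bivariate IP-kernel Granger causality index source → target."""
    config = config or GCConfig()
    if config.kernel != "inhomogeneous_polynomial":
        raise ValueError("bkgc requires the inhomogeneous_polynomial kernel")
    design = _pairwise_design(source, target, config.m)
    return fdr_filtered_index(design, build_gram_pair(design, config), config, **kw)


def _multivariate_design(data: np.ndarray, source: int, target: int, m: int) -> LaggedDesign:
    lag_blocks = []
    x = None
    for i, row in enumerate(data):
        lags, tgt = embed(row, m)
        lag_blocks.append(lags)
        if i == target:
            x = tgt
    restricted = np.vstack([b for i, b in enumerate(lag_blocks) if i != source])
    full = np.vstack(lag_blocks)
    return LaggedDesign(restricted, full, x)


def mkgc(
    series: RegionSeriesSet | np.ndarray,
    source: int,
    target: int,
    config: GCConfig | None = None,
    **kw,
) -> CausalityIndex:
    """Multivariate IP-kernel Granger causality source → target given all others.

    The restricted model regresses the target's future on the past of every
    observed series except the candidate driver; the full model adds the
    driver.  Conditioning on the remaining series is what lets the index
    distinguish direct influence from influence mediated by a third signal.
    With only two series this reduces to :func:`bkgc` by construction.
    """
    config = config or GCConfig()
    data = series.data if isinstance(series, RegionSeriesSet) else np.atleast_2d(series)
    if data.shape[0] < 2:
        raise ValueError("mkgc needs at least 2 series")
    if source == target:
        raise ValueError("source and target must differ")
    design = _multivariate_design(data, source, target, config.m)
    return fdr_filtered_index(design, build_gram_pair(design, config), config, **kw)


@dataclass(frozen=True)
class CausalityMatrix:
    """Directed weighted adjacency of filtered GC indices; entry (i, j) = δF(i→j)."""

    labels: tuple
    W: np.ndarray
    method: str = "mkgc"
    config: GCConfig | None = None

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        W = np.asarray(self.W, dtype=float)
        n = len(labels)
        if W.shape != (n, n):
            raise ValueError("W must be square with one row per label")
        if np.any(np.abs(np.diagonal(W)) > 0):
            raise ValueError("diagonal must be zero")
        if np.any(W < -1e-12) or np.any(W > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "W", W)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.W, index=list(self.labels), columns=list(self.labels))

    def to_edge_frame(self):
        import pandas as pd

        rows = [
            (self.labels[i], self.labels[j], self.W[i, j])
            for i in range(len(self.labels))
            for j in range(len(self.labels))
            if i != j
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


_METHODS = ("blgc", "bkgc", "mkgc")


def causality_matrix(
    series: RegionSeriesSet,
    method: str = "mkgc",
    config: GCConfig | None = None,
) -> CausalityMatrix:
    """Evaluate the chosen GC index for all ordered pairs of series."""
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if config is None:
        config = GCConfig(kernel="linear") if method == "blgc" else GCConfig()
    data = series.data
    r = data.shape[0]
    if r < 2:
        raise ValueError("need at least 2 series")
    W = np.zeros((r, r))
    for i in range(r):
        for j in range(r):
            if i == j:
                continue
            try:
                if method == "blgc":
                    idx = blgc(data[i], data[j], config)
                elif method == "bkgc":
                    idx = bkgc(data[i], data[j], config)
                else:
                    idx = mkgc(series, i, j, config)
            except Exception as exc:  # annotate with the offending pair
                raise RuntimeError(
                    f"{method} failed for pair {series.labels[i]}->{series.labels[j]}: {exc}"
                ) from exc
            W[i, j] = idx.value
    return CausalityMatrix(series.labels, W, method=method, config=config)


def select_order_bic(series: RegionSeriesSet | np.ndarray, max_m: int = 10) -> int:
    """Select the autoregression order by BIC of a linear VAR fit.

    The kernel model has no closed-form likelihood, so the order is chosen on
    the linear vector-autoregressive surrogate: fit VAR(m) for m = 1…max_m and
    return the BIC-minimizing order (never below 1).
    """
    from statsmodels.tsa.api import VAR

    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    data = series.data if isinstance(series, RegionSeriesSet) else np.atleast_2d(series)
    if data.shape[1] <= max_m + data.shape[0] * max_m + 1:
        raise ValueError("series too short for the requested maximum order")
    if max_m == 1:
        return 1
    model = VAR(np.ascontiguousarray(data.T))
    sel = model.select_order(maxlags=max_m, trend="c")
    return max(int(sel.bic), 1)
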