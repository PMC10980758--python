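"""Comparator feature-selection methods benchmarked against DELVE.

All selectors share the :class:`~trajselect.containers.ExpressionMatrix`
contract and return either a :class:`FeatureRanking` or a selected feature
set. Graph-based selectors reuse :mod:`trajselect.graph`; clustering,
regression and eigendecomposition go through scikit-learn / scipy.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.linear_model import Lars

from .containers import ExpressionMatrix, FeatureRanking, ParameterError, rank_features
from .graph import NeighborGraph, build_affinity_graph, graph_laplacian, laplacian_score
from .graph import _knn

logger = logging.getLogger(__name__)


def max_variance_rank(X: ExpressionMatrix) -> FeatureRanking:
    """Rank features by descending sample variance (ddof=1)."""
    var = X.values.var(axis=0, ddof=1)
    return FeatureRanking(
        order=[X.feature_ids[i] for i in np.argsort(-var, kind="stable")],
        scores=np.sort(var)[::-1],
        method="max_variance",
        ascending=False,
    )


def minimum_connected_k(points: np.ndarray, k_max: int | None = None) -> int:
    """Smallest k whose symmetrized k-NN graph is a single component."""
    n = points.shape[0]
    k_max = n - 1 if k_max is None else k_max
    idx_full, _ = _knn(points, k_max)
    rows = np.repeat(np.arange(n), k_max)
    for k in range(1, k_max + 1):
        adj = sp.csr_matrix(
            (np.ones(n * k), (np.repeat(np.arange(n), k), idx_full[:, :k].ravel())), shape=(n, n)
        )
        adj = adj.maximum(adj.T)
        if connected_components(adj, directed=False, return_labels=False) == 1:
            return k
    raise ParameterError("k-NN graph never becomes connected")


def neighborhood_variance_select(X: ExpressionMatrix, k_c: int | None = None) -> list[str]:
    """Select gradually-varying features by the neighborhood-variance ratio.

    The neighborhood variance of feature f sums squared differences between
    every cell and its k_c nearest neighbors, normalized by (n*k_c - 1),
    where k_c is the minimum k giving a fully connected graph. Features with
    global variance / neighborhood variance > 1 are selected; globally
    constant features are excluded.
    """
    values = X.values
    n = values.shape[0]
    if k_c is None:
        k_c = minimum_connected_k(values)
    idx, _ = _knn(values, k_c)
    diffs = values[:, None, :] - values[idx]  # (n, k_c, d)
    nbhd_var = (diffs**2).sum(axis=(0, 1)) / (n * k_c - 1)
    global_var = values.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = global_var / nbhd_var
    selected = (global_var > 0) & (nbhd_var > 0) & (ratio > 1.0)
    return [X.feature_ids[j] for j in np.flatnonzero(selected)]


def hvg_select(X: ExpressionMatrix, p_select: int, n_bins: int = 20) -> list[str]:
    """Highly variable features by binned normalized dispersion.

    Dispersion (variance/mean) is z-scored within equal-frequency bins of
    mean expression; the top ``p_select`` features by normalized dispersion
    are returned. Bins with fewer than 2 features merge into a neighbor.
    """
    if p_select > X.n_features:
        raise ParameterError("p_select exceeds number of features")
    values = X.values
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    d = len(mean)
    n_bins = min(n_bins, d)
    # equal-frequency bins of mean expression
    order = np.argsort(mean, kind="stable")
    bins = np.empty(d, dtype=int)
    bins[order] = np.minimum(np.arange(d) * n_bins // d, n_bins - 1)
    # merge undersized bins leftwards so every bin has >= 2 members
    for b in range(n_bins):
        if 0 < np.sum(bins == b) < 2:
            target = b - 1 if b > 0 else b + 1
            logger.info("merging HVG bin %d (size < 2) into bin %d", b, target)
            bins[bins == b] = target

    z = np.zeros(d)
    for b in np.unique(bins):
        members = bins == b
        mu, sd = disp[members].mean(), disp[members].std(ddof=1)
        z[members] = (disp[members] - mu) / sd if sd > 0 else 0.0
    top = np.argsort(-z, kind="stable")[:p_select]
    return [X.feature_ids[j] for j in top]


def laplacian_score_rank(X: ExpressionMatrix, k: int = 10, seed: int = 0) -> FeatureRanking:
    """Laplacian-score baseline: full-feature graph, ascending score."""
    G = build_affinity_graph(X, k=k, seed=seed)
    scores = laplacian_score(X, G)
    return rank_features(X.feature_ids, scores, method="laplacian_score", ascending=True)


# ---------------------------------------------------------------------------
# Hotspot-style local autocorrelation
# ---------------------------------------------------------------------------

def _hotspot_weights(values: np.ndarray, k: int, kernel_half: bool = False) -> sp.csr_matrix:
    """Row-stochastic Gaussian neighbor weights with bandwidth at the
    ceil(k/3)-th neighbor; the kernel exponent omits the 1/2 factor unless
    ``kernel_half`` harmonizes it with the affinity-graph kernel."""
    n = values.shape[0]
    idx, dist = _knn(values, k)
    bw_nbr = int(np.ceil(k / 3))
    sigma = dist[:, bw_nbr - 1].copy()
    zero = sigma <= 0
    if zero.any():
        for i in np.flatnonzero(zero):
            positive = dist[i][dist[i] > 0]
            sigma[i] = positive.min() if positive.size else np.finfo(float).eps
    denom = 2.0 * sigma**2 if kernel_half else sigma**2
    w = np.exp(-(dist**2) / denom[:, None])
    w = w / w.sum(axis=1, keepdims=True)  # sum_j w_ij = 1 per cell
    rows = np.repeat(np.arange(n), k)
    return sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))


def _standardize_normal(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = np.zeros_like(values, dtype=float)
    ok = sd > 0
    out[:, ok] = (values[:, ok] - mean[ok]) / sd[ok]
    return out


def _standardize_negative_binomial(counts: np.ndarray) -> np.ndarray:
    """Standardize counts under a per-gene NB null with library-size offsets.

    Size factors scale each gene's mean per cell; the gene dispersion is
    moment-matched on size-factor-corrected counts. Genes whose moment fit
    degenerates (variance <= mean) fall back to the normal standardization.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    size_factor = totals / max(totals.mean(), 1e-300)
    scaled = counts / size_factor[:, None]
    mu = scaled.mean(axis=0)
    var = scaled.var(axis=0, ddof=1)
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        if mu[j] <= 0:
            continue
        mu_ij = mu[j] * size_factor
        if var[j] > mu[j]:
            phi = (var[j] - mu[j]) / mu[j] ** 2
            var_ij = mu_ij + phi * mu_ij**2
        else:
            logger.debug("NB moment fit degenerate for gene %d; normal fallback", j)
            var_ij = np.full_like(mu_ij, max(var[j], 1e-300))
        out[:, j] = (counts[:, j] - mu_ij) / np.sqrt(var_ij)
    return out


def hotspot_rank(
    X: ExpressionMatrix,
    k: int = 10,
    null_model: str = "normal",
    kernel_half: bool = False,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by local autocorrelation H_f = sum_{i != j} w_ij f_i f_j.

    ``f`` is the feature standardized under the chosen null (``normal`` or,
    for counts, ``negative_binomial``); high positive H_f marks features
    whose expression is coherent across neighboring cells.
    """
    if null_model not in ("normal", "negative_binomial"):
        raise ParameterError(f"unknown null model {null_model!r}")
    if null_model == "negative_binomial" and X.layer != "counts":
        raise ParameterError("negative_binomial null requires a counts layer")
    W = _hotspot_weights(X.values, k, kernel_half=kernel_half)
    W = W - sp.diags(W.diagonal())  # exclude i == j terms
    F = (
        _standardize_negative_binomial(X.values)
        if null_model == "negative_binomial"
        else _standardize_normal(X.values)
    )
    H = np.einsum("ij,ij->j", F, W @ F)
    return rank_features(
        X.feature_ids,
        H,
        method="hotspot",
        ascending=False,
        params={"k": k, "null_model": null_model},
    )


# ---------------------------------------------------------------------------
# Multi-cluster feature selection (spectral embedding + LARS)
# ---------------------------------------------------------------------------

def mcfs_rank(
    X: ExpressionMatrix,
    K_eigvecs: int,
    p_select: int,
    k: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """MCFS: regress Laplacian eigenvectors on features, score by max |coef|.

    Solves the generalized eigenproblem L y = lambda D y, keeps the
    ``K_eigvecs`` smallest nontrivial eigenvectors, runs least-angle
    regression of each on X stopping at ``p_select`` nonzero coefficients,
    and scores feature j by max_k |a_{k,j}| (descending).
    """
    if K_eigvecs < 1:
        raise ParameterError("K_eigvecs must be >= 1")
    if p_select < 1 or p_select > X.n_features:
        raise ParameterError("p_select out of range")
    G = build_affinity_graph(X, k=k, seed=seed)
    L, D = graph_laplacian(G)
    n_comp = connected_components(G.weights, directed=False, return_labels=False)
    if n_comp > 1:
        logger.warning("affinity graph has %d components; eigenvectors span components", n_comp)
    n = L.shape[0]
    n_eig = min(K_eigvecs + 1, n - 1)
    # shift-invert near 0 targets the smallest generalized eigenvalues
    vals, vecs = spla.eigsh(
        L.asfptype(), k=n_eig, M=D.asfptype(), sigma=-1e-6, which="LM"
    )
    order = np.argsort(vals)
    # drop only the trivial global-constant mode; on a disconnected graph the
    # remaining null modes are component indicators and carry cluster structure
    vecs = vecs[:, order][:, 1:]
    if vecs.shape[1] == 0:
        raise ParameterError("no nontrivial eigenvectors available")

    Xc = X.values - X.values.mean(axis=0)
    scores = np.zeros(X.n_features)
    for kk in range(vecs.shape[1]):
        y = vecs[:, kk] - vecs[:, kk].mean()
        lars = Lars(n_nonzero_coefs=p_select)
        lars.fit(Xc, y)
        scores = np.maximum(scores, np.abs(lars.coef_))
    return rank_features(
        X.feature_ids,
        scores,
        method="mcfs",
        ascending=False,
        params={"K_eigvecs": K_eigvecs, "p_select": p_select, "k": k},
    )


def random_rank(X: ExpressionMatrix, seed: int = 0) -> FeatureRanking:
    """Uniformly random feature permutation (the null selector)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.n_features)
    return FeatureRanking(
        order=[X.feature_ids[i] for i in perm],
        scores=np.arange(X.n_features, dtype=float),
        method="random",
        ascending=True,
        params={"seed": seed},
    )
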