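"""Weighted k-NN affinity graphs and graph-signal smoothness functionals.

Cells are connected to their k nearest neighbors (Euclidean distance,
optionally in PCA space) and edges carry Gaussian weights

    w_ij = exp(-||x_i - x_j||^2 / (2 sigma_i^2)),   j in N_i,

with an adaptive per-cell bandwidth sigma_i equal to the distance from cell
i to its 3rd nearest neighbor. The directed relation is symmetrized with
W <- max(W, W^T), which keeps every defined edge at full weight. On top of
the graph the module provides neighborhood averaging, the unnormalized
Laplacian L = D - W, the total-variation quadratic form f^T L f, and the
Laplacian score used for feature ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix, ParameterError, StructuralError

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """A symmetrized Gaussian-weighted k-NN graph over cells.

    Attributes
    ----------
    neighbor_index
        ``(n, k)`` int array; row i lists the k nearest neighbors of cell i
        (self excluded), nearest first, ties broken by lowest cell index.
    neighbor_dist
        Euclidean distances aligned with ``neighbor_index``.
    bandwidth
        Per-cell Gaussian bandwidth sigma_i (> 0).
    weights
        ``(n, n)`` sparse symmetric CSR matrix of edge weights in (0, 1].
    """

    neighbor_index: np.ndarray
    neighbor_dist: np.ndarray
    bandwidth: np.ndarray
    weights: sp.csr_matrix

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_index.shape[1]

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


def _knn(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact k-NN excluding self, deterministic lowest-index tie-break."""
    n = points.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n), algorithm="brute").fit(points)
    dist, idx = nn.kneighbors(points)
    # drop self wherever it appears (it may not be first among duplicates)
    out_idx = np.empty((n, k), dtype=int)
    out_dist = np.empty((n, k), dtype=float)
    for i in range(n):
        row_idx, row_dist = idx[i], dist[i]
        keep = row_idx != i
        # stable re-sort by (distance, index) for a deterministic order
        order = np.lexsort((row_idx[keep], row_dist[keep]))
        out_idx[i] = row_idx[keep][order][:k]
        out_dist[i] = row_dist[keep][order][:k]
    return out_idx, out_dist


def build_affinity_graph(
    X: ExpressionMatrix | np.ndarray,
    k: int,
    n_pcs: int | None = None,
    bandwidth_neighbor: int = 3,
    seed: int = 0,
) -> NeighborGraph:
    """Build the Gaussian-weighted k-NN affinity graph over cells.

    Parameters
    ----------
    X
        Expression matrix (cells x features) or a raw array.
    k
        Number of nearest neighbors (k < n).
    n_pcs
        If given, distances are computed on the first ``n_pcs`` principal
        components (centered, unscaled).
    bandwidth_neighbor
        sigma_i is the distance from cell i to this neighbor (1-based;
        default the 3rd nearest neighbor).
    seed
        Seed for the PCA solver; graph construction is otherwise exact.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n = values.shape[0]
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the number of cells n={n}")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if bandwidth_neighbor < 1 or bandwidth_neighbor >= n:
        raise ParameterError("bandwidth_neighbor must be in [1, n-1]")
    points = values
    if n_pcs is not None:
        if n_pcs > min(values.shape):
            raise ParameterError(f"n_pcs={n_pcs} exceeds min(n, d)={min(values.shape)}")
        points = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(values)

    # the bandwidth neighbor may lie beyond the k-th neighbor
    idx_full, dist_full = _knn(points, max(k, bandwidth_neighbor))
    idx, dist = idx_full[:, :k], dist_full[:, :k]
    sigma = dist_full[:, bandwidth_neighbor - 1].copy()
    if np.any(sigma <= 0):
        n_zero = int(np.sum(sigma <= 0))
        for i in np.flatnonzero(sigma <= 0):
            positive = dist_full[i][dist_full[i] > 0]
            sigma[i] = positive.min() if positive.size else np.finfo(float).eps
        logger.warning(
            "zero bandwidth for %d cell(s) (duplicate points); substituted the "
            "smallest positive neighbor distance",
            n_zero,
        )

    w = np.exp(-(dist**2) / (2.0 * sigma[:, None] ** 2))
    rows = np.repeat(np.arange(n), k)
    W = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    W = W.maximum(W.T)  # symmetrize keeping full edge weights
    W.eliminate_zeros()
    return NeighborGraph(neighbor_index=idx, neighbor_dist=dist, bandwidth=sigma, weights=W.tocsr())


def neighborhood_average(X: ExpressionMatrix | np.ndarray, G: NeighborGraph) -> np.ndarray:
    """Per-cell average expression over the k nearest neighbors (self excluded).

    Returns the ``(n, d)`` matrix Z whose row i is the unweighted mean of the
    neighbor rows of cell i.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if values.shape[0] != G.n_cells:
        raise StructuralError(
            f"matrix has {values.shape[0]} cells but graph has {G.n_cells} nodes"
        )
    return values[G.neighbor_index].mean(axis=1)


def graph_laplacian(G: NeighborGraph) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Unnormalized Laplacian L = D - W and the diagonal degree matrix D."""
    W = G.weights
    if (abs(W - W.T) > 1e-12).nnz:
        raise StructuralError("weight matrix is not symmetric")
    deg = np.asarray(W.sum(axis=1)).ravel()
    D = sp.diags(deg, format="csr")
    return (D - W).tocsr(), D


def total_variation(f: np.ndarray, G: NeighborGraph) -> float:
    """Total variation f^T L f of a graph signal.

    Equals sum_{i<j} w_ij (f_i - f_j)^2 over the symmetrized edges; zero for
    constant signals.
    """
    f = np.asarray(f, dtype=float).ravel()
    if f.shape[0] != G.n_cells:
        raise StructuralError("signal length does not match graph size")
    if not np.all(np.isfinite(f)):
        raise StructuralError("signal contains non-finite values")
    L, _ = graph_laplacian(G)
    return float(f @ (L @ f))


def laplacian_score(F: ExpressionMatrix | np.ndarray, G: NeighborGraph) -> np.ndarray:
    """Laplacian score of every feature column on graph G (lower = smoother).

    Each feature f is degree-centered, f~ = f - (f^T D 1)/(1^T D 1), and
    scored as (f~^T L f~) / (f~^T D f~). Features with zero degree-weighted
    variance get +inf so an ascending sort places them last.
    """
    values = F.values if isinstance(F, ExpressionMatrix) else np.asarray(F, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != G.n_cells:
        raise StructuralError("feature matrix rows do not match graph size")
    if G.weights.nnz == 0:
        raise StructuralError("graph has no edges")
    L, D = graph_laplacian(G)
    deg = D.diagonal()
    total_deg = deg.sum()
    center = (deg @ values) / total_deg
    Ft = values - center  # degree-weighted centering
    num = np.einsum("ij,ij->j", Ft, L @ Ft)
    den = np.einsum("ij,ij->j", Ft, deg[:, None] * Ft)
    scores = np.full(values.shape[1], np.inf)
    ok = den > 1e-12 * max(total_deg, 1.0)
    scores[ok] = num[ok] / den[ok]
    return scores
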