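"""Trajectory-preservation metrics and the selector benchmarking harness.

Metrics cover the three stages at which feature selection can help or hurt
trajectory analysis: biological relevance of the chosen features
(precision@k), cell-state recovery (k-NN / SVM classification, KMeans++
clustering scored by NMI), and trajectory reconstruction (diffusion
pseudotime correlation, cluster-graph Jaccard distance). A permutation test
against a protein-association score matrix checks whether a feature module
is enriched for experimentally supported interactions.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, SVR

from .containers import ExpressionMatrix, ParameterError, StructuralError

logger = logging.getLogger(__name__)

Selector = Callable[[ExpressionMatrix], Sequence[str]]


def precision_at_k(selected: Sequence[str], reference: set[str], k: int) -> float:
    """Fraction of the top-k selected features present in the reference set."""
    if k < 1 or k > len(selected):
        raise ParameterError(f"k={k} out of range for {len(selected)} selected features")
    top = list(selected)[:k]
    return len(set(top) & set(reference)) / k


def knn_classify_cv(
    X: ExpressionMatrix,
    labels: np.ndarray,
    selector: Selector | None = None,
    k_clf: int = 3,
    n_folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold k-NN classification accuracy with per-fold selection.

    When ``selector`` is given it is refit on each training fold and returns
    the feature ids used by that fold's classifier; otherwise all columns of
    ``X`` are used. Returns one accuracy per fold.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ParameterError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} members "
            f"(< n_folds={n_folds})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(X.values, labels)):
        if selector is not None:
            train_matrix = ExpressionMatrix(
                X.values[tr], [X.cell_ids[i] for i in tr], list(X.feature_ids), X.layer
            )
            cols = X.feature_indices(selector(train_matrix))
        else:
            cols = np.arange(X.n_features)
        clf = KNeighborsClassifier(n_neighbors=k_clf)
        clf.fit(X.values[np.ix_(tr, cols)], labels[tr])
        accs.append(clf.score(X.values[np.ix_(te, cols)], labels[te]))
    return np.asarray(accs)


def svm_eval(
    X_selected: np.ndarray,
    target: np.ndarray,
    mode: str = "classify",
    n_folds: int = 10,
    seed: int = 0,
    param_grid: dict | None = None,
    max_refolds: int = 5,
) -> np.ndarray:
    """Nested-CV SVM evaluation: accuracy (classify) or RMSE (regress).

    The inner loop grid-searches the regularization strength (and kernel
    width); the outer loop yields one score per fold.
    """
    if mode not in ("classify", "regress"):
        raise ParameterError(f"unknown mode {mode!r}")
    X_selected = np.asarray(X_selected, dtype=float)
    target = np.asarray(target)
    grid = param_grid or {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]}

    for attempt in range(max_refolds):
        fold_seed = seed + attempt
        if mode == "classify":
            outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        else:
            outer = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        try:
            scores = []
            for tr, te in outer.split(X_selected, target if mode == "classify" else None):
                if mode == "classify" and len(np.unique(target[tr])) < 2:
                    raise ParameterError("degenerate single-class training fold")
                est = SVC() if mode == "classify" else SVR()
                search = GridSearchCV(est, grid, cv=3, n_jobs=1)
                search.fit(X_selected[tr], target[tr])
                pred = search.predict(X_selected[te])
                if mode == "classify":
                    scores.append(float(np.mean(pred == target[te])))
                else:
                    scores.append(float(np.sqrt(np.mean((pred - target[te]) ** 2))))
            return np.asarray(scores)
        except ParameterError:
            logger.warning("degenerate fold with seed %d; refolding", fold_seed)
    raise ParameterError("could not produce non-degenerate folds")


def cluster_nmi(
    X_selected: np.ndarray,
    labels: np.ndarray,
    n_clusters: int,
    n_init: int = 25,
    seed: int = 0,
    denominator: str = "sum",
) -> np.ndarray:
    """NMI between KMeans++ partitions and reference labels, one per init.

    ``denominator="sum"`` is the standard arithmetic-mean normalization
    2 I / (H(u) + H(v)); ``"product"`` evaluates the literal 2 I / (H(u) H(v)).
    A degenerate single-cluster partition scores 0.
    """
    X_selected = np.asarray(X_selected, dtype=float)
    labels = np.asarray(labels)
    out = np.empty(n_init)
    for i in range(n_init):
        pred = KMeans(n_clusters=n_clusters, init="k-means++", n_init=1, random_state=seed + i).fit_predict(X_selected)
        if len(np.unique(pred)) < 2 or len(np.unique(labels)) < 2:
            out[i] = 0.0
        elif denominator == "sum":
            out[i] = normalized_mutual_info_score(labels, pred, average_method="arithmetic")
        elif denominator == "product":
            out[i] = _nmi_product(labels, pred)
        else:
            raise ParameterError(f"unknown denominator {denominator!r}")
    return out


def _nmi_product(u: np.ndarray, v: np.ndarray) -> float:
    """Literal 2 I(u;v) / (H(u) H(v)) from the joint contingency table."""
    table = pd.crosstab(pd.Series(u), pd.Series(v)).to_numpy(dtype=float)
    joint = table / table.sum()
    pu, pv = joint.sum(axis=1), joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pu, pv)[nz])))
    hu = -float(np.sum(pu[pu > 0] * np.log(pu[pu > 0])))
    hv = -float(np.sum(pv[pv > 0] * np.log(pv[pv > 0])))
    if hu == 0 or hv == 0:
        return 0.0
    return 2.0 * mi / (hu * hv)


def dpt_pseudotime(
    X_selected: np.ndarray,
    root: int | Sequence[int],
    n_comps: int = 20,
    k: int = 10,
) -> np.ndarray:
    """Diffusion pseudotime of every cell from one or more root cells.

    A k-NN kernel on the selected features feeds a diffusion map
    (``n_comps`` components); pseudotime accumulates transition distance
    from the root (0 at the root). The diffusion map is computed once and
    re-rooted for every requested root; a scalar root returns a vector, a
    sequence returns a ``(n_roots, n)`` array. Disconnected cells come back
    infinite and are flagged with a warning.
    """
    import anndata as ad
    import scanpy as sc

    X_selected = np.asarray(X_selected, dtype=float)
    n = X_selected.shape[0]
    roots = [int(root)] if np.isscalar(root) else [int(r) for r in root]
    if any(not 0 <= r < n for r in roots):
        raise ParameterError(f"root index out of range for {n} cells")
    adata = ad.AnnData(X=X_selected.copy())
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X")
    sc.tl.diffmap(adata, n_comps=min(n_comps, n - 1))
    # a degenerate spectrum can leave fewer usable components than requested
    n_dcs = min(n_comps, adata.obsm["X_diffmap"].shape[1])
    out = np.empty((len(roots), n))
    for i, r in enumerate(roots):
        adata.uns["iroot"] = r
        adata.obs.drop(columns=["dpt_pseudotime"], errors="ignore", inplace=True)
        sc.tl.dpt(adata, n_dcs=n_dcs)
        out[i] = np.asarray(adata.obs["dpt_pseudotime"], dtype=float)
    if not np.all(np.isfinite(out)):
        logger.warning(
            "graph is disconnected; %d pseudotime values are infinite",
            int(np.sum(~np.isfinite(out))),
        )
    return out[0] if np.isscalar(root) else out


def kendall_tau(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation (tau-b)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StructuralError("vectors must have equal length")
    return float(scipy.stats.kendalltau(a, b).statistic)


def cluster_connectivity(
    weights, labels: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Cluster-level trajectory graph from a cell graph.

    Edge strength between clusters a and b is the observed inter-cluster
    edge weight divided by its expectation when the same total weight is
    placed uniformly over cell pairs (proportional to cluster sizes). With
    ``threshold`` the matrix is binarized into an adjacency.
    """
    import scipy.sparse as sp

    labels = np.asarray(labels)
    clusters = np.unique(labels)
    K = len(clusters)
    W = sp.coo_matrix(weights)
    n = W.shape[0]
    sizes = np.array([np.sum(labels == c) for c in clusters], dtype=float)
    idx_of = {c: i for i, c in enumerate(clusters)}
    observed = np.zeros((K, K))
    for i, j, w in zip(W.row, W.col, W.data):
        if i < j:
            observed[idx_of[labels[i]], idx_of[labels[j]]] += w
    observed = observed + observed.T
    total = observed.sum() / 2.0
    pair_counts = np.outer(sizes, sizes)
    np.fill_diagonal(pair_counts, sizes * (sizes - 1) / 2.0)
    all_pairs = n * (n - 1) / 2.0
    expected = total * pair_counts / all_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        conn = np.where(expected > 0, observed / expected, 0.0)
    np.fill_diagonal(conn, 0.0)
    if threshold is not None:
        conn = (conn > threshold).astype(float)
    return conn


def trajectory_graph_jaccard(W_p: np.ndarray, W_r: np.ndarray) -> float:
    """Jaccard distance between two cluster-level trajectory graphs.

    Graphs are compared as undirected edge sets (any positive entry is an
    edge); identical graphs give 0, disjoint edge sets give 1, and two
    empty graphs give 0 by convention.
    """
    W_p, W_r = np.asarray(W_p), np.asarray(W_r)
    if W_p.shape != W_r.shape:
        raise StructuralError("adjacency matrices must have equal shape")

    def edges(W):
        i, j = np.nonzero(np.triu(W, k=1))
        return set(zip(i.tolist(), j.tolist()))

    ep, er = edges(W_p), edges(W_r)
    if not ep and not er:
        return 0.0
    return 1.0 - len(ep & er) / len(ep | er)


def string_permutation_test(
    assoc: np.ndarray,
    query: np.ndarray,
    R: int = 1000,
    seed: int = 0,
    threshold: float = 0.0,
    statistic: str = "average_degree",
) -> float:
    """Permutation p-value for association-network enrichment of a feature set.

    The observed statistic is the average degree (2|E|/|N|) of the subnetwork
    induced by the query features, counting edges whose association score
    exceeds ``threshold``; the null redraws same-size feature sets uniformly
    R times and p = (N + 1)/(R + 1) with N the number of null draws at least
    as connected as the query. ``statistic="literal"`` uses |N|/|E| instead
    (so sparser networks score higher) with the same counting rule.
    """
    assoc = np.asarray(assoc, dtype=float)
    d = assoc.shape[0]
    if assoc.shape[0] != assoc.shape[1]:
        raise StructuralError("association matrix must be square")
    query = np.asarray(query, dtype=int)
    if query.size == 0:
        raise ParameterError("query set must be nonempty")
    if query.size > d:
        raise ParameterError("query larger than feature space")

    def stat(idx: np.ndarray) -> float:
        sub = assoc[np.ix_(idx, idx)]
        n_edges = np.sum(np.triu(sub, k=1) > threshold)
        if statistic == "average_degree":
            return 2.0 * n_edges / len(idx)
        if statistic == "literal":
            return len(idx) / n_edges if n_edges > 0 else np.inf
        raise ParameterError(f"unknown statistic {statistic!r}")

    t_obs = stat(query)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(R):
        draw = rng.choice(d, size=query.size, replace=False)
        if stat(draw) >= t_obs:
            n_ge += 1
    return (n_ge + 1) / (R + 1)


def aggregate_scores(medians: pd.DataFrame) -> pd.DataFrame:
    """Rank methods by the mean of min-max scaled per-dataset scores.

    ``medians`` holds one median metric value per method (rows) and dataset
    (columns). Each column is min-max scaled across methods (a constant
    column — including the single-method case — scales to 1.0); the
    aggregate is the row mean, ranked descending.
    """
    if medians.shape[0] == 1:
        logger.warning("single method: scaled scores defined as 1.0")
    scaled = medians.copy().astype(float)
    for col in scaled.columns:
        lo, hi = scaled[col].min(), scaled[col].max()
        scaled[col] = 1.0 if hi == lo else (scaled[col] - lo) / (hi - lo)
    out = pd.DataFrame({"aggregate": scaled.mean(axis=1)})
    out["rank"] = out["aggregate"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank")
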