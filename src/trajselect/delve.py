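"""DELVE: dynamic selection of locally covarying features.

The method ranks features by how smoothly they vary along an approximate
cellular trajectory, built in two steps.

Step 1 (dynamic seed selection)
    A k-NN affinity graph over cells is built from all features; each cell
    is replaced by the average expression of its neighborhood; kernel
    herding picks m representative neighborhoods; the average pairwise
    change in expression across those neighborhoods,

        Delta = (1/(m-1)) sum_i (Z~ - j_m z~_i^T),

    is clustered feature-wise (KMeans++ on Delta^T) into c modules. A module
    is called dynamic when the average sample variance of its features'
    Delta columns exceeds the same statistic for randomly drawn feature
    sets of equal size (permutation test, t draws). The whole clustering +
    test is repeated across n_runs KMeans++ initializations and the dynamic
    seed is the intersection of dynamically flagged features across runs.

Step 2 (feature ranking)
    A new affinity graph over all cells is built from the seed features
    only; every original feature is then scored by its Laplacian score on
    that seeded graph and ranked ascending (smooth features first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix, FeatureRanking, ParameterError, StructuralError, rank_features
from .graph import NeighborGraph, build_affinity_graph, laplacian_score, neighborhood_average
from .sketch import SketchIndex, kernel_herd_sketch

logger = logging.getLogger(__name__)


class EmptySeedError(RuntimeError):
    """Raised when no feature survives the dynamic-module intersection.

    Lower the number of modules ``c`` (coarser modules are likelier to pool
    coordinated features) or raise the permutation count ``t``; silently
    ranking on all features would defeat the purpose of seeding.
    """


# ---------------------------------------------------------------------------
# Step 1 primitives
# ---------------------------------------------------------------------------

def delta_matrix(Z_sketch: np.ndarray) -> np.ndarray:
    """Average pairwise change in expression across sketched neighborhoods.

    Implements the literal sum Delta = (1/(m-1)) sum_{i=1..m} (Z~ - j_m z~_i^T),
    which reduces algebraically to (m/(m-1)) * (Z~ - column means of Z~).
    Every column of the result sums to zero.
    """
    Z = np.asarray(Z_sketch, dtype=float)
    m = Z.shape[0]
    if m < 2:
        raise ParameterError(f"need at least 2 sketched neighborhoods, got {m}")
    # literal sum over i: sum_i (Z - j z_i^T) = m Z - j (sum_i z_i)^T
    total = Z.sum(axis=0)
    return (m * Z - np.ones((m, 1)) @ total[None, :]) / (m - 1)


def cluster_feature_dynamics(Delta: np.ndarray, c: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Cluster features into c modules by their Delta profiles.

    KMeans++ on the rows of Delta^T (one length-m profile per feature).
    Each call keeps the best of ``n_init`` initializations; repeated calls
    with different seeds give the independent clustering runs whose dynamic
    features are intersected.
    """
    Delta = np.asarray(Delta, dtype=float)
    d = Delta.shape[1]
    if c < 1 or c > d:
        raise ParameterError(f"number of modules c={c} must be in [1, d={d}]")
    km = KMeans(n_clusters=c, init="k-means++", n_init=n_init, random_state=seed)
    return km.fit_predict(Delta.T)


def dynamic_module_test(
    Delta: np.ndarray,
    labels: np.ndarray,
    t: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of coordinated dynamics per feature module.

    For module c the statistic is the mean over its features of the sample
    variance (ddof=1) of the feature's Delta column. The null draws |P_c|
    features uniformly without replacement from all d features, t times,
    and averages the same statistic. A module is dynamic iff its observed
    statistic strictly exceeds the null mean.

    Returns a DataFrame indexed by module with columns
    ``cluster_variance``, ``null_variance``, ``dynamic``, ``n_features``.
    """
    Delta = np.asarray(Delta, dtype=float)
    labels = np.asarray(labels, dtype=int)
    d = Delta.shape[1]
    if labels.shape[0] != d:
        raise StructuralError("labels length does not match feature count")
    if t < 1:
        raise ParameterError("permutation count t must be >= 1")
    col_var = Delta.var(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    rows = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # pragma: no cover - unique() precludes this
            raise StructuralError(f"module {c} is empty")
        observed = col_var[members].mean()
        # null: mean variance of t random feature sets of the same size
        draws = np.empty(t)
        for q in range(t):
            draws[q] = col_var[rng.choice(d, size=members.size, replace=False)].mean()
        null = draws.mean()
        rows.append(
            {
                "module": int(c),
                "cluster_variance": float(observed),
                "null_variance": float(null),
                "dynamic": bool(observed > null),
                "n_features": int(members.size),
            }
        )
    return pd.DataFrame(rows).set_index("module")


@dataclass
class ModuleResult:
    """Per-run module assignments, permutation verdicts, and the seed set."""

    labels: np.ndarray  # (n_runs, d) feature -> module per run
    module_tables: list[pd.DataFrame]  # one permutation-test table per run
    seed_features: list[str]
    feature_ids: list[str]
    n_permutations: int
    n_runs: int
    sketch: SketchIndex | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: feature_id, run, module, dynamic_flag."""
        rows = []
        for r in range(self.n_runs):
            dyn = self.module_tables[r]["dynamic"]
            for j, f in enumerate(self.feature_ids):
                m = int(self.labels[r, j])
                rows.append(
                    {"feature_id": f, "run": r, "module": m, "dynamic_flag": bool(dyn.loc[m])}
                )
        return pd.DataFrame(rows)


def select_dynamic_seed(
    X: ExpressionMatrix,
    k: int = 10,
    m: int = 1000,
    c: int = 5,
    t: int = 1000,
    n_runs: int = 10,
    n_pcs: int | None = None,
    seed: int = 0,
    graph: NeighborGraph | None = None,
) -> ModuleResult:
    """Step 1 end to end: graph -> Z -> sketch -> Delta -> modules -> seed.

    The sketch is computed once and shared across the ``n_runs`` clustering
    repetitions; only the KMeans++ initialization (and the permutation
    draws) vary between runs. The dynamic seed is the intersection across
    runs of features assigned to a dynamic module.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    if graph is None:
        graph = build_affinity_graph(X, k=k, n_pcs=n_pcs, seed=seed)
    Z = neighborhood_average(X, graph)
    m_eff = min(m, X.n_cells)
    sketch = kernel_herd_sketch(Z, m=m_eff, seed=seed)
    Delta = delta_matrix(Z[sketch.indices])

    d = X.n_features
    labels = np.empty((n_runs, d), dtype=int)
    tables: list[pd.DataFrame] = []
    seed_mask = np.ones(d, dtype=bool)
    for r in range(n_runs):
        labels[r] = cluster_feature_dynamics(Delta, c=c, seed=seed + 1 + r)
        table = dynamic_module_test(Delta, labels[r], t=t, seed=seed + 101 + r)
        tables.append(table)
        dyn_modules = set(table.index[table["dynamic"]])
        seed_mask &= np.isin(labels[r], list(dyn_modules))

    seed_features = [X.feature_ids[j] for j in np.flatnonzero(seed_mask)]
    if not seed_features:
        logger.warning(
            "dynamic seed intersection is EMPTY after %d runs; consider lowering c "
            "or raising t before ranking",
            n_runs,
        )
    return ModuleResult(
        labels=labels,
        module_tables=tables,
        seed_features=seed_features,
        feature_ids=list(X.feature_ids),
        n_permutations=t,
        n_runs=n_runs,
        sketch=sketch,
    )


# ---------------------------------------------------------------------------
# Step 2
# ---------------------------------------------------------------------------

def delve_rank(
    X: ExpressionMatrix,
    seed_features: list[str],
    k: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """Rank all features by Laplacian score on the seed-feature graph.

    The graph is rebuilt over all n cells using only the seed-feature
    columns (bandwidth = 3rd-NN distance as in step 1); every original
    feature is then scored on that graph and sorted ascending.
    """
    if not seed_features:
        raise EmptySeedError(
            "cannot rank on an empty dynamic seed; lower c or raise t in step 1"
        )
    missing = set(seed_features) - set(X.feature_ids)
    if missing:
        raise StructuralError(f"seed features not in the matrix: {sorted(missing)[:5]}")
    seeded = X.subset_features(list(seed_features))
    G = build_affinity_graph(seeded, k=k, seed=seed)
    scores = laplacian_score(X, G)
    return rank_features(
        X.feature_ids,
        scores,
        method="delve",
        ascending=True,
        seed_features=list(seed_features),
        params={"k": k, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class DELVE:
    """DELVE feature-selection model over an expression matrix.

    Parameters
    ----------
    data
        :class:`ExpressionMatrix` (or anything ``from_dataframe`` accepts).
    k
        Neighbors in the cell affinity graph (default 10).
    m
        Number of herded neighborhoods (default 1000; capped at n).
    c
        Number of feature modules for KMeans++ (no universal default in the
        method; 3 suits the simulated trajectories here, larger values suit
        richer panels).
    t
        Permutation draws in the dynamic-module test (default 1000).
    n_runs
        Clustering initializations whose dynamic features are intersected
        (default 10).
    n_pcs
        Optional PCA dimension for step-1 graph distances.

    Examples
    --------
    >>> model = DELVE(expr, c=3)
    >>> res = model.fit(seed=0)
    >>> res.ranking.top(100)
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        k: int = 10,
        m: int = 1000,
        c: int = 5,
        t: int = 1000,
        n_runs: int = 10,
        n_pcs: int | None = None,
    ):
        if not isinstance(data, ExpressionMatrix):
            data = ExpressionMatrix.from_dataframe(pd.DataFrame(data))
        self.data = data
        self.k = k
        self.m = m
        self.c = c
        self.t = t
        self.n_runs = n_runs
        self.n_pcs = n_pcs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DELVE":
        return cls(ExpressionMatrix.from_dataframe(df), **kwargs)

    def fit(self, seed: int = 0) -> "DELVEResults":
        """Run both steps and return the fitted results."""
        graph = build_affinity_graph(self.data, k=self.k, n_pcs=self.n_pcs, seed=seed)
        modules = select_dynamic_seed(
            self.data,
            k=self.k,
            m=self.m,
            c=self.c,
            t=self.t,
            n_runs=self.n_runs,
            n_pcs=self.n_pcs,
            seed=seed,
            graph=graph,
        )
        ranking = delve_rank(self.data, modules.seed_features, k=self.k, seed=seed)
        return DELVEResults(model=self, modules=modules, ranking=ranking, graph=graph, seed=seed)


@dataclass
class DELVEResults:
    """Fitted DELVE artifacts: dynamic seed, module table, feature ranking."""

    model: DELVE
    modules: ModuleResult
    ranking: FeatureRanking
    graph: NeighborGraph
    seed: int

    @property
    def seed_features(self) -> list[str]:
        return self.modules.seed_features

    def top(self, p: int) -> list[str]:
        return self.ranking.top(p)

    def summary(self) -> str:
        m = self.model
        lines = [
            "DELVE feature selection results",
            "=" * 45,
            f"cells: {m.data.n_cells}    features: {m.data.n_features}",
            f"k={m.k}  m={m.m}  c={m.c}  t={m.t}  n_runs={m.n_runs}  seed={self.seed}",
            f"dynamic seed: {len(self.seed_features)} / {m.data.n_features} features",
            "",
            "top 10 ranked features (ascending Laplacian score):",
        ]
        seed_set = set(self.seed_features)
        for f, s in zip(self.ranking.order[:10], self.ranking.scores[:10]):
            mark = "*" if f in seed_set else " "
            lines.append(f"  {mark} {f:<24s} {s:10.6f}")
        lines.append("(* = member of the dynamic seed)")
        return "\n".join(lines)


def delve(
    X: ExpressionMatrix,
    k: int = 10,
    n_pcs: int | None = None,
    m: int = 1000,
    c: int = 5,
    t: int = 1000,
    n_runs: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """Functional one-call interface; see :class:`DELVE` for parameters."""
    res = DELVE(X, k=k, m=m, c=c, t=t, n_runs=n_runs, n_pcs=n_pcs).fit(seed=seed)
    ranking = res.ranking
    ranking.params.update({"m": m, "c": c, "t": t, "n_runs": n_runs})
    return ranking
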