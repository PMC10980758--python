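"""Simulation benchmark harness: DELVE vs baselines on linear trajectories.

Reproduces the simulation study protocol: for each signal-to-noise
condition, simulate linear-trajectory count data sets, run a selector, and
score the top genes by stratified 3-fold k-NN classification (selection
refit on each training fold), top-k precision against the ground-truth DE
genes, and diffusion-pseudotime Kendall correlation to the latent step.

Protocol constants (the study conditions): 1500 cells x 500 genes, 6
clusters, 10 data sets per condition, top 100 genes, DELVE with k=10,
m=1000, c=3 on a 50-PC graph, counts median-library normalized and log1p
transformed before selection and evaluation. The same data-set seeds are
reused across noise conditions, so each condition adds noise to the same
underlying reference trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .baselines import random_rank
from .containers import ExpressionMatrix
from .delve import DELVE, EmptySeedError
from .evaluate import dpt_pseudotime, kendall_tau, knn_classify_cv, precision_at_k
from .simulate import SimParams, normalize_counts, simulate_trajectory

logger = logging.getLogger(__name__)

TOP_P = 100
N_PCS = 50
DELVE_KW = dict(k=10, m=1000, c=3, t=1000, n_runs=10, n_pcs=N_PCS)


@dataclass
class ConditionResult:
    """Per-condition benchmark outcome across simulated data sets."""

    bcv: float
    fold_accuracies: list[float] = field(default_factory=list)  # all folds, all data sets
    dataset_accuracies: list[float] = field(default_factory=list)  # per-dataset fold median
    random_dataset_accuracies: list[float] = field(default_factory=list)
    precisions: list[float] = field(default_factory=list)
    random_expectations: list[float] = field(default_factory=list)  # DE fraction per data set
    seed_de_fractions: list[float] = field(default_factory=list)
    dataset_taus: list[float] = field(default_factory=list)

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.fold_accuracies))

    @property
    def median_tau(self) -> float:
        return float(np.median(self.dataset_taus))


def _fit_delve(train: ExpressionMatrix, seed: int):
    """Fit DELVE, following the documented empty-seed guidance.

    An empty dynamic-seed intersection is first retried with fresh
    clustering seeds, then with a coarser module count (c=2, the "lower c"
    guidance). Returns None when every attempt fails.
    """
    for c, attempt in [(DELVE_KW["c"], 0), (DELVE_KW["c"], 1), (2, 0), (2, 1)]:
        try:
            kw = {**DELVE_KW, "c": c}
            return DELVE(train, **kw).fit(seed=seed + 7919 * attempt)
        except EmptySeedError:
            logger.warning(
                "empty dynamic seed (c=%d, attempt %d); retrying per guidance", c, attempt
            )
    return None


def _fit_delve_top(train: ExpressionMatrix, seed: int, top_p: int = TOP_P) -> list[str]:
    """Top features from DELVE, with a loud Laplacian-score last resort."""
    res = _fit_delve(train, seed)
    if res is not None:
        return res.top(top_p)
    logger.warning("dynamic seed empty after all retries; falling back to Laplacian score")
    from .baselines import laplacian_score_rank

    return laplacian_score_rank(train, k=DELVE_KW["k"], seed=seed).top(top_p)


def run_linear_condition(
    bcv: float,
    base_seed: int,
    n_datasets: int = 10,
    compute_accuracy: bool = True,
    compute_tau: bool = False,
    compute_random_baseline: bool = False,
    refit_folds: bool = True,
    top_p: int = TOP_P,
) -> ConditionResult:
    """Benchmark DELVE on ``n_datasets`` simulated linear trajectories."""
    result = ConditionResult(bcv=bcv)
    for ds in range(n_datasets):
        seed = int(base_seed + ds)
        sim = simulate_trajectory(SimParams(bcv=bcv, seed=seed))
        n, d = sim.counts.shape
        X = ExpressionMatrix(
            normalize_counts(sim.counts),
            [f"cell_{i}" for i in range(n)],
            [f"gene_{j}" for j in range(d)],
            "normalized",
        )
        de_genes = {f"gene_{j}" for j in sim.de_genes}
        result.random_expectations.append(len(de_genes) / d)

        res = _fit_delve(X, seed)
        if res is not None:
            top = res.top(top_p)
            seed_set = set(res.seed_features)
        else:
            logger.warning("dataset %d: empty seed after retries; Laplacian-score fallback", ds)
            from .baselines import laplacian_score_rank

            top = laplacian_score_rank(X, k=DELVE_KW["k"], seed=seed).top(top_p)
            seed_set = set()
        result.precisions.append(precision_at_k(top, de_genes, top_p))
        result.seed_de_fractions.append(
            len(seed_set & de_genes) / len(seed_set) if seed_set else 0.0
        )

        if compute_accuracy:
            # drop classes too small for stratified 3-fold CV
            labels = sim.cluster_label
            classes, counts = np.unique(labels, return_counts=True)
            keep = np.isin(labels, classes[counts >= 3])
            if not keep.all():
                logger.warning("dropping %d cells in undersized clusters", int((~keep).sum()))
            X_keep = ExpressionMatrix(
                X.values[keep],
                [X.cell_ids[i] for i in np.flatnonzero(keep)],
                list(X.feature_ids),
                X.layer,
            )
            kept_labels = labels[keep]
            if refit_folds:
                selector = lambda train: _fit_delve_top(train, seed, top_p)  # noqa: E731
                accs = knn_classify_cv(
                    X_keep, kept_labels, selector=selector, k_clf=3, n_folds=3, seed=seed
                )
            else:
                accs = knn_classify_cv(
                    X_keep.subset_features(top), kept_labels, k_clf=3, n_folds=3, seed=seed
                )
            result.fold_accuracies.extend(float(a) for a in accs)
            result.dataset_accuracies.append(float(np.median(accs)))

            if compute_random_baseline:
                rand_top = random_rank(X, seed=seed).top(top_p)
                rand_accs = knn_classify_cv(
                    X_keep.subset_features(rand_top), kept_labels, k_clf=3, n_folds=3, seed=seed
                )
                result.random_dataset_accuracies.append(float(np.median(rand_accs)))

        if compute_tau:
            roots = np.argsort(sim.step, kind="stable")[:10]
            pts = dpt_pseudotime(X.subset_features(top).values, roots, n_comps=20, k=10)
            taus = [kendall_tau(pt, sim.step) for pt in pts]
            result.dataset_taus.append(float(np.median(taus)))
        logger.info(
            "bcv=%.2f dataset %d done (precision %.3f)", bcv, ds, result.precisions[-1]
        )
    return result
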