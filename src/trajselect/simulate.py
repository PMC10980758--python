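"""Gamma-Poisson path-trajectory count simulator.

Emulates splatter-style differentiation trajectories: base gene means are
gamma-distributed (with rare log-normal outliers), each path segment marks a
subset of genes as differentially expressed with log-normal fold factors,
cell means interpolate linearly along their segment, expected counts are
rescaled to log-normal library sizes, biological noise enters through a
mean-dependent BCV dispersion (gamma-mixed Poisson), and technical dropout
thins counts binomially with retention exp(-lambda * mu_i^2).

Three noise knobs map onto real degradations of single-cell RNA-seq data:
``bcv`` (stochastic gene expression), ``lib_loc`` (sequencing depth) and
``dropout_lambda`` (capture inefficiency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, ParameterError

# Topologies: parent of each cluster segment (-1 = origin).
TOPOLOGIES = {
    "linear": [-1, 0, 1, 2, 3, 4],
    "bifurcation": [-1, 0, 1, 2, 1, 4],
    "tree": [-1, 0, 0, 1, 1, 2],
}

# mu_i in the dropout model is log1p of the per-gene mean count after cell
# totals are normalized to this target. The value was fixed once by the
# calibration routine below so that lambda = 0.05 / 0.1 thin roughly 10% /
# 20% of counts under the default simulation parameters.
DEFAULT_DROPOUT_NORM_TARGET = 650.0


@dataclass
class SimParams:
    """Simulation parameters; defaults are the fitted values used throughout.

    ``mean_rate``/``mean_shape`` parameterize the gamma prior on base gene
    means, ``lib_loc``/``lib_scale`` the log-normal library sizes (natural
    log scale), ``out_*`` the expression-outlier mechanism, ``bcv``/``bcv_df``
    the biological coefficient of variation, and ``dropout_lambda`` the
    binomial undersampling intensity.
    """

    topology: str = "linear"
    n_cells: int = 1500
    n_genes: int = 500
    n_clusters: int = 6
    mean_rate: float = 0.0173
    mean_shape: float = 0.54
    lib_loc: float = 12.6
    lib_scale: float = 0.423
    out_prob: float = 0.000342
    out_fac_loc: float = 0.1
    out_fac_scale: float = 0.4
    bcv: float = 0.1
    bcv_df: float = 90.2
    dropout_lambda: float = 0.0
    de_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    de_down_prob: float = 0.5
    nonlinear_prob: float = 0.1
    sigma_fac: float = 0.8
    cluster_dirichlet_conc: float = 1.0
    skew_beta: tuple[float, float] = (10.0, 10.0)
    n_steps: int = 100
    dropout_norm_target: float = DEFAULT_DROPOUT_NORM_TARGET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ParameterError(
                f"unknown topology {self.topology!r}; choose from {sorted(TOPOLOGIES)}"
            )
        if self.n_clusters != len(TOPOLOGIES[self.topology]):
            raise ParameterError(
                f"topology {self.topology!r} defines {len(TOPOLOGIES[self.topology])} clusters"
            )
        for name in ("mean_rate", "mean_shape", "lib_scale", "bcv", "bcv_df"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("out_prob", "de_prob", "de_down_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability")
        if self.dropout_lambda < 0:
            raise ParameterError("dropout_lambda must be >= 0")


@dataclass
class SimulatedTrajectory:
    """Counts plus the ground-truth reference the simulator produces."""

    counts: np.ndarray  # (n_cells, n_genes) integer counts
    cluster_label: np.ndarray  # (n_cells,) segment membership
    step: np.ndarray  # (n_cells,) monotone progression along each path
    de_flags: np.ndarray  # (n_genes, n_clusters) DE per path segment
    params: SimParams
    gene_means: np.ndarray = field(default=None, repr=False)  # base means

    @property
    def de_genes(self) -> np.ndarray:
        """Indices of genes DE along at least one path segment."""
        return np.flatnonzero(self.de_flags.any(axis=1))

    def to_expression_matrix(self) -> ExpressionMatrix:
        n, d = self.counts.shape
        return ExpressionMatrix(
            self.counts.astype(float),
            [f"cell_{i}" for i in range(n)],
            [f"gene_{j}" for j in range(d)],
            layer="counts",
        )


def _cluster_depths(parents: list[int]) -> np.ndarray:
    depths = np.zeros(len(parents), dtype=int)
    for c, p in enumerate(parents):
        depths[c] = 0 if p < 0 else depths[p] + 1
    return depths


def simulate_trajectory(params: SimParams) -> SimulatedTrajectory:
    """Simulate one trajectory data set from the gamma-Poisson path model."""
    rng = np.random.default_rng(params.seed)
    n, d, K = params.n_cells, params.n_genes, params.n_clusters
    parents = TOPOLOGIES[params.topology]

    # (1) base gene means with rare outliers
    base = rng.gamma(shape=params.mean_shape, scale=1.0 / params.mean_rate, size=d)
    is_outlier = rng.random(d) < params.out_prob
    if is_outlier.any():
        factors = rng.lognormal(params.out_fac_loc, params.out_fac_scale, size=is_outlier.sum())
        base[is_outlier] = np.median(base) * factors

    # (2) per-segment DE genes with log-normal fold factors (half down)
    de_flags = rng.random((d, K)) < params.de_prob
    de_factors = np.ones((d, K))
    n_de = int(de_flags.sum())
    fac = rng.lognormal(params.de_fac_loc, params.de_fac_scale, size=n_de)
    down = rng.random(n_de) < params.de_down_prob
    fac[down] = 1.0 / fac[down]
    de_factors[de_flags] = fac

    # per-segment per-step fold factors: each segment starts at its parent's
    # endpoint factor (origin = 1) and ends at that factor times its own DE
    # factors (fold changes are relative to the segment's origin, so they
    # compound along a lineage), interpolating linearly over the step grid;
    # a random subset of genes instead follows a Brownian bridge between the
    # same endpoints (nonlinear dynamics)
    S = params.n_steps
    frac = (np.arange(S) + 0.5) / S
    fac_end = np.empty((K, d))
    fac_path = np.empty((K, S, d))
    for c, p in enumerate(parents):  # parents precede children in TOPOLOGIES
        start = np.ones(d) if p < 0 else fac_end[p]
        end = start * de_factors[:, c]
        fac_end[c] = end
        fac_path[c] = start[None, :] + frac[:, None] * (end - start)[None, :]
        nonlin = rng.random(d) < params.nonlinear_prob
        for j in np.flatnonzero(nonlin):
            fac_path[c, :, j] = _brownian_bridge(
                start[j], end[j], S, params.sigma_fac, rng
            )

    # (3) cells: Dirichlet cluster probabilities; step sampled from a linear
    # probability gradient running from skew to 1 - skew across the grid
    probs = rng.dirichlet(np.full(K, params.cluster_dirichlet_conc))
    cluster = rng.choice(K, size=n, p=probs)
    skew = rng.beta(*params.skew_beta, size=K)
    step_idx = np.empty(n, dtype=int)
    for c in range(K):
        members = np.flatnonzero(cluster == c)
        step_probs = np.linspace(skew[c], 1.0 - skew[c], S)
        step_probs = np.maximum(step_probs, 0.0)
        step_probs /= step_probs.sum()
        step_idx[members] = rng.choice(S, size=members.size, p=step_probs)
    pos = (step_idx + 0.5) / S

    mu_cell = base[None, :] * fac_path[cluster, step_idx]

    # (4) rescale per-cell expected counts to log-normal library sizes
    lib = rng.lognormal(params.lib_loc, params.lib_scale, size=n)
    row_tot = mu_cell.sum(axis=1)
    mu_cell = mu_cell * (lib / np.maximum(row_tot, 1e-300))[:, None]

    # (5) BCV dispersion: gamma-mixed Poisson with mean-dependent dispersion
    chi = rng.chisquare(params.bcv_df, size=d)
    disp = (params.bcv + 1.0 / np.sqrt(np.maximum(mu_cell, 1e-300))) * np.sqrt(
        params.bcv_df / chi
    )[None, :]
    shape = 1.0 / disp**2
    trended = rng.gamma(shape=shape, scale=mu_cell * disp**2)
    counts = rng.poisson(trended).astype(np.int64)

    # (6) technical dropout
    if params.dropout_lambda > 0:
        counts = apply_dropout(
            counts,
            params.dropout_lambda,
            seed=params.seed + 1,
            norm_target=params.dropout_norm_target,
        )

    # monotone progression: segment depth plus within-segment position
    depths = _cluster_depths(parents)
    step = depths[cluster] + pos

    return SimulatedTrajectory(
        counts=counts,
        cluster_label=cluster,
        step=step,
        de_flags=de_flags,
        params=params,
        gene_means=base,
    )


def _brownian_bridge(
    start: float, end: float, n_steps: int, sigma_fac: float, rng: np.random.Generator
) -> np.ndarray:
    """Positive Brownian bridge between two fold factors over the step grid."""
    sigma = rng.uniform(0.0, sigma_fac * 0.5 * (abs(start) + abs(end)))
    dt = 1.0 / max(n_steps - 1, 1)
    walk = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sigma, n_steps - 1) * np.sqrt(dt))])
    t = np.linspace(0.0, 1.0, n_steps)
    bridge = start + walk - t * (walk[-1] - (end - start))
    return np.maximum(bridge, 1e-6)


def apply_dropout(
    counts: np.ndarray,
    lambda_: float,
    seed: int = 0,
    norm_target: float = DEFAULT_DROPOUT_NORM_TARGET,
) -> np.ndarray:
    """Binomial undersampling with mean-dependent retention.

    Per gene i the retention probability is r_i = exp(-lambda * mu_i^2) with
    mu_i = log1p of the gene's mean count after normalizing every cell total
    to ``norm_target``; each count is replaced by Binomial(count, r_i).
    lambda = 0 leaves the matrix untouched.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ParameterError("counts must be nonnegative")
    if lambda_ < 0:
        raise ParameterError("lambda must be >= 0")
    if lambda_ == 0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    normalized = counts / totals * norm_target
    mu = np.log1p(normalized.mean(axis=0))
    retention = np.exp(-lambda_ * mu**2)
    return rng.binomial(counts.astype(np.int64), retention[None, :])


def realized_undersampling(
    counts: np.ndarray, lambda_: float, norm_target: float = DEFAULT_DROPOUT_NORM_TARGET
) -> float:
    """Expected fraction of total counts removed by ``apply_dropout``.

    Reported by the calibration routine; useful for mapping lambda onto an
    undersampling percentage for a given data set.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    normalized = counts / totals * norm_target
    mu = np.log1p(normalized.mean(axis=0))
    retention = np.exp(-lambda_ * mu**2)
    gene_tot = counts.sum(axis=0)
    return float(1.0 - (retention * gene_tot).sum() / max(gene_tot.sum(), 1.0))


def normalize_counts(counts: np.ndarray, transform: str | None = "log1p") -> np.ndarray:
    """Median-library normalization with a variance-stabilizing transform.

    Cell totals are scaled to the median library size, then ``log1p``
    (default), ``sqrt`` or no transform is applied. This is the standard
    preprocessing applied before feature selection on count data.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    scaled = counts / totals * np.median(counts.sum(axis=1))
    if transform is None:
        return scaled
    if transform == "sqrt":
        return np.sqrt(scaled)
    if transform == "log1p":
        return np.log1p(scaled)
    raise ParameterError(f"unknown transform {transform!r}")
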