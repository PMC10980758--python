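"""Core in-memory containers shared across the package.

The central object is :class:`ExpressionMatrix`, a thin validated wrapper
around a dense cells x features matrix with string identifiers. It is
deliberately lighter than :class:`anndata.AnnData` (no layers, no obs/var
frames) because every algorithm in this package consumes exactly one matrix
plus ids; converters to and from AnnData and pandas are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class StructuralError(ValueError):
    """Raised when inputs violate a structural contract (shape, ids, graph)."""


class ParameterError(ValueError):
    """Raised when a hyperparameter is outside its valid range."""


@dataclass
class ExpressionMatrix:
    """A validated cells x features expression matrix.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_features)`` float array. Counts or normalized
        intensities; no missing or non-finite entries allowed.
    cell_ids, feature_ids
        Unique string identifiers for rows and columns.
    layer
        ``"counts"`` (nonnegative integers) or ``"normalized"``.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    layer: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise StructuralError(f"need n >= 2 cells and d >= 1 features, got {n} x {d}")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.cell_ids) != n:
            raise StructuralError("cell_ids length does not match row count")
        if len(self.feature_ids) != d:
            raise StructuralError("feature_ids length does not match column count")
        if len(set(self.cell_ids)) != n:
            raise StructuralError("cell_ids are not unique")
        if len(set(self.feature_ids)) != d:
            raise StructuralError("feature_ids are not unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise StructuralError(
                f"non-finite entry at cell {self.cell_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        if self.layer not in ("counts", "normalized"):
            raise ParameterError(f"unknown layer {self.layer!r}")
        if self.layer == "counts":
            if (self.values < 0).any():
                i, j = np.argwhere(self.values < 0)[0]
                raise StructuralError(
                    f"negative count at cell {self.cell_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
            if not np.allclose(self.values, np.round(self.values)):
                raise StructuralError("counts layer must contain integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_indices(self, feature_ids: Iterable[str]) -> np.ndarray:
        """Map feature ids to 0-based column indices (order preserved)."""
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([lookup[f] for f in feature_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise StructuralError(f"unknown feature id {e.args[0]!r}") from None

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.feature_indices(feature_ids)
        return ExpressionMatrix(
            self.values[:, idx], list(self.cell_ids), [self.feature_ids[i] for i in idx], self.layer
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, layer: str | None = None) -> "ExpressionMatrix":
        """Build from a cells-as-rows DataFrame (index = cell ids)."""
        values = df.to_numpy(dtype=float)
        if layer is None:
            layer = "counts" if _looks_like_counts(values) else "normalized"
        return cls(values, list(map(str, df.index)), list(map(str, df.columns)), layer)

    @classmethod
    def from_anndata(cls, adata, layer: str | None = None) -> "ExpressionMatrix":
        import scipy.sparse as sp

        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=float)
        if layer is None:
            layer = "counts" if _looks_like_counts(X) else "normalized"
        return cls(X, list(map(str, adata.obs_names)), list(map(str, adata.var_names)), layer)

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(X=self.values.copy())
        adata.obs_names = self.cell_ids
        adata.var_names = self.feature_ids
        return adata

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_ids)


def _looks_like_counts(values: np.ndarray) -> bool:
    return bool(np.all(values >= 0) and np.allclose(values, np.round(values)))


@dataclass
class FeatureRanking:
    """An ordered ranking of all features produced by a selector.

    ``order`` lists feature ids from best to worst; ``scores`` is aligned
    with ``order``. For ascending-is-better criteria (Laplacian score) the
    scores increase along ``order``; for descending criteria (variance,
    autocorrelation) they decrease. ``ascending`` records the convention.
    """

    order: list[str]
    scores: np.ndarray
    method: str
    ascending: bool = True
    seed_features: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.order) != len(self.scores):
            raise StructuralError("order and scores length mismatch")
        if len(set(self.order)) != len(self.order):
            raise StructuralError("ranking contains duplicate feature ids")

    def top(self, p: int) -> list[str]:
        if p > len(self.order):
            raise ParameterError(f"requested top {p} of {len(self.order)} features")
        return self.order[:p]

    def to_frame(self) -> pd.DataFrame:
        seed = set(self.seed_features)
        return pd.DataFrame(
            {
                "feature_id": self.order,
                "score": self.scores,
                "rank": np.arange(1, len(self.order) + 1),
                "in_dynamic_seed": [f in seed for f in self.order],
            }
        )


def rank_features(
    feature_ids: Sequence[str],
    scores: np.ndarray,
    *,
    method: str,
    ascending: bool,
    **extra,
) -> FeatureRanking:
    """Sort features by score with a deterministic tie-break on input order.

    NaN scores (undefined statistics) sort last regardless of direction.
    """
    scores = np.asarray(scores, dtype=float)
    key = scores if ascending else -scores
    key = np.where(np.isnan(key), np.inf, key)
    idx = np.argsort(key, kind="stable")
    return FeatureRanking(
        order=[feature_ids[i] for i in idx],
        scores=scores[idx],
        method=method,
        ascending=ascending,
        **extra,
    )
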