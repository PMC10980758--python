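"""Readers and writers for expression matrices, rankings and reports.

Cells are rows everywhere; indices are 0-based internally and outputs carry
feature ids, never indices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, FeatureRanking, ParameterError, StructuralError


@dataclass
class RunConfig:
    """Serializable run configuration; one master seed drives everything."""

    input_path: str = ""
    input_format: str = "tsv"
    layer: str | None = None
    method: str = "delve"
    k: int = 10
    m: int = 1000
    c: int = 5
    t: int = 1000
    n_pcs: int | None = None
    top_p: int = 100
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        else:
            path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def load_expression(
    path: str | Path, format: str | None = None, layer: str | None = None
) -> ExpressionMatrix:
    """Load a cells x features matrix from TSV/CSV, an MTX directory or h5ad.

    The layer is inferred (nonnegative integers -> counts) unless given.
    An MTX directory must contain ``matrix.mtx`` plus ``cells.tsv`` and
    ``features.tsv`` id files (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {
            ".tsv": "tsv",
            ".csv": "csv",
            ".h5ad": "h5ad",
        }.get(path.suffix, "mtx_dir" if path.is_dir() else None)
        if format is None:
            raise ParameterError(f"cannot infer format for {path}")

    if format in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",", index_col=0)
        bad = df.isna()
        if bad.to_numpy().any():
            i = int(np.argwhere(bad.to_numpy())[0][0])
            j = int(np.argwhere(bad.to_numpy())[0][1])
            raise StructuralError(
                f"missing value at cell {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        return ExpressionMatrix.from_dataframe(df, layer=layer)
    if format == "mtx_dir":
        import scipy.io

        candidates = [path / "matrix.mtx", *sorted(path.glob("*.mtx"))]
        mtx = next((p for p in candidates if p.exists()), None)
        if mtx is None:
            raise FileNotFoundError(path / "matrix.mtx")
        values = np.asarray(scipy.io.mmread(mtx).todense(), dtype=float)
        cells = _read_ids(path, ("cells.tsv",), "cell_id")
        feats = _read_ids(path, ("features.tsv", "genes.tsv"), "feature_id")
        if layer is None:
            layer = "counts" if np.allclose(values, np.round(values)) and values.min() >= 0 else "normalized"
        return ExpressionMatrix(values, cells, feats, layer)
    if format == "h5ad":
        import anndata as ad

        return ExpressionMatrix.from_anndata(ad.read_h5ad(path), layer=layer)
    raise ParameterError(f"unknown format {format!r}")


def _read_ids(directory: Path, names: tuple[str, ...], id_column: str) -> list[str]:
    """Read row/column ids from an id file: either one bare id per line or a
    TSV with a header containing ``id_column``."""
    for name in names:
        p = directory / name
        if p.exists():
            first = p.read_text().splitlines()[0]
            if "\t" in first or id_column in first:
                df = pd.read_csv(p, sep="\t")
                col = id_column if id_column in df.columns else df.columns[0]
                return [str(v) for v in df[col]]
            return p.read_text().split()
    raise FileNotFoundError(directory / names[0])


def save_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    """Write a ranking as TSV plus a JSON sidecar with params and version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ranking.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = {
        "method": ranking.method,
        "ascending": ranking.ascending,
        "seed_features": list(ranking.seed_features),
        "params": {k: _jsonable(v) for k, v in ranking.params.items()},
        "package_version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_ranking(path: str | Path) -> FeatureRanking:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureRanking(
        order=[str(f) for f in df["feature_id"]],
        scores=df["score"].to_numpy(),
        method=sidecar["method"],
        ascending=sidecar["ascending"],
        seed_features=sidecar["seed_features"],
        params=sidecar["params"],
    )


def save_report(report: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a metrics table as TSV with a JSON sidecar of run parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, sep="\t", index=False)
    sidecar = {"params": {k: _jsonable(v) for k, v in (params or {}).items()},
               "package_version": __version__}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def save_simulation(sim, out_dir: str | Path) -> None:
    """Write a simulated trajectory: MTX counts, cell/gene metadata, params."""
    import scipy.io
    import scipy.sparse as sp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "counts.mtx", sp.coo_matrix(sim.counts))
    n, d = sim.counts.shape
    pd.DataFrame(
        {"cell_id": [f"cell_{i}" for i in range(n)], "cluster": sim.cluster_label, "step": sim.step}
    ).to_csv(out / "cells.tsv", sep="\t", index=False)
    gene_meta = pd.DataFrame({"feature_id": [f"gene_{j}" for j in range(d)]})
    for c in range(sim.de_flags.shape[1]):
        gene_meta[f"de_path_{c}"] = sim.de_flags[:, c]
    gene_meta.to_csv(out / "genes.tsv", sep="\t", index=False)
    (out / "params.json").write_text(
        json.dumps({k: _jsonable(v) for k, v in asdict(sim.params).items()}, indent=2, sort_keys=True)
    )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    return v
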