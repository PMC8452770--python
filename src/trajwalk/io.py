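"""Readers and writers for matrices, graphs and result tables.

Delimited matrices carry an explicit first column of cell ids and a header
row of feature ids; Matrix Market files use ``<stem>.cells.txt`` /
``<stem>.features.txt`` sidecars; h5ad containers are read through anndata.
All numeric text is written with 17 significant digits so csv/mtx round
trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError
from .graphs import ClusterAssignment, ClusterGraph, FeatureMatrix

_FLOAT_FMT = "%.17g"


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(
        suffix, "csv"
    )


def read_matrix(path: str | Path, format: str | None = None) -> FeatureMatrix:
    """Load a cells x features matrix from csv/tsv/mtx/h5ad."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise FormatError(f"malformed {fmt} file {path}: {exc}") from exc
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)].tolist()[:3]
            raise FormatError(f"{path}: missing values in rows {rows}")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entries ({exc})") from exc
        return FeatureMatrix(values, df.index.to_numpy(object), df.columns.to_numpy(object))
    if fmt == "mtx":
        M = scipy.io.mmread(path).tocsr()
        cells_file = path.with_suffix("").with_suffix(".cells.txt")
        feats_file = path.with_suffix("").with_suffix(".features.txt")
        cell_ids = feat_ids = None
        if cells_file.exists():
            cell_ids = np.loadtxt(cells_file, dtype=str, ndmin=1).astype(object)
            if len(cell_ids) != M.shape[0]:
                raise FormatError(
                    f"{cells_file}: {len(cell_ids)} ids for {M.shape[0]} matrix rows"
                )
        if feats_file.exists():
            feat_ids = np.loadtxt(feats_file, dtype=str, ndmin=1).astype(object)
            if len(feat_ids) != M.shape[1]:
                raise FormatError(
                    f"{feats_file}: {len(feat_ids)} ids for {M.shape[1]} matrix columns"
                )
        return FeatureMatrix.from_array(M, cell_ids, feat_ids)
    if fmt == "h5ad":
        import anndata

        ad = anndata.read_h5ad(path)
        X = ad.X.toarray() if sp.issparse(ad.X) else np.asarray(ad.X)
        return FeatureMatrix(
            X.astype(float), ad.obs_names.to_numpy(object), ad.var_names.to_numpy(object)
        )
    raise FormatError(f"unknown format {fmt!r}")


def write_matrix(fm: FeatureMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(fm.dense(), index=fm.cell_ids, columns=fm.feature_ids)
        df.index.name = "cell_id"
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(fm.dense()))
        np.savetxt(path.with_suffix("").with_suffix(".cells.txt"), fm.cell_ids, fmt="%s")
        np.savetxt(path.with_suffix("").with_suffix(".features.txt"), fm.feature_ids, fmt="%s")
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def write_cluster_assignment(a: ClusterAssignment, cell_ids, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "cluster": a.labels}).to_csv(path, index=False)


def write_cluster_graph(cg: ClusterGraph, path: str | Path) -> None:
    rows = [{"source": i, "target": j, "weight": w} for i, j, w in cg.edges()]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_directed_graph(dg, path: str | Path) -> None:
    rows = []
    src, dst = np.nonzero(dg.W_undirected > 0)
    for i, j in zip(src.tolist(), dst.tolist()):
        rows.append(
            {
                "source": i,
                "target": j,
                "weight": dg.W_directed[i, j],
                "multiplier": dg.multipliers[i, j],
            }
        )
    pd.DataFrame(rows, columns=["source", "target", "weight", "multiplier"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_pseudotime(pt_df: pd.DataFrame, path: str | Path) -> None:
    pt_df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(path: str | Path, config: dict, extra: dict | None = None) -> None:
    import trajwalk

    payload = {
        "package": "trajwalk",
        "version": trajwalk.__version__,
        "numpy": np.__version__,
        "config": config,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
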