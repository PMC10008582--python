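"""Readers and writers for the standard expression-matrix formats.

Supported formats: H5AD (annotated-matrix HDF5 container, via anndata),
MatrixMarket MTX triplet (10x-style ``matrix.mtx`` + ``features.tsv`` +
``barcodes.tsv``), and dense CSV/TSV with one header row and one index
column. Gene identity is the uppercase symbol string; duplicate symbols are
collapsed by summing their columns.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io

from .types import FormatError, SingleCellDataset, canonical_gene_symbol

log = logging.getLogger(__name__)

_GENE_RE = re.compile(r"^[A-Z0-9][A-Z0-9.\-_]*$")
_BARCODE_RE = re.compile(r"^[ACGT]{8,}(-\d+)?$")


def _gene_axis_score(labels) -> float:
    """Fraction of labels that look like gene symbols rather than cell ids."""
    labels = [str(x) for x in labels]
    score = 0
    for s in labels:
        u = s.upper()
        if _BARCODE_RE.match(u) or "CELL" in u or "BARCODE" in u or "SPOT" in u:
            continue
        if _GENE_RE.match(u) and any(c.isalpha() for c in u):
            score += 1
    return score / max(len(labels), 1)


def _collapse_duplicate_genes(X: np.ndarray, symbols: list[str]):
    canon = [canonical_gene_symbol(s) for s in symbols]
    if len(set(canon)) == len(canon):
        return X, canon
    order: dict[str, int] = {}
    for s in canon:
        order.setdefault(s, len(order))
    uniq = [None] * len(order)
    for s, i in order.items():
        uniq[i] = s
    out = np.zeros((X.shape[0], len(order)), dtype=X.dtype)
    for j, s in enumerate(canon):
        out[:, order[s]] += X[:, j]
    log.warning(
        "collapsed %d duplicate gene symbols by sum", len(canon) - len(order)
    )
    return out, uniq


def _finalize(
    X: np.ndarray,
    genes: list[str],
    cell_ids: list[str],
    labels: list[str] | None,
    label_key: str | None,
) -> SingleCellDataset:
    X, genes = _collapse_duplicate_genes(np.asarray(X, dtype=float), genes)
    if labels is None:
        if label_key is not None:
            raise FormatError(f"labels requested under {label_key!r} but none found")
        labels = ["unknown"] * X.shape[0]
    return SingleCellDataset(
        counts=X,
        gene_symbols=genes,
        cell_types=[str(x) for x in labels],
        cell_ids=[str(x) for x in cell_ids],
    )


def _read_csv(path: Path, label_key, orientation: str) -> SingleCellDataset:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "auto":
        row_score = _gene_axis_score(df.index)
        col_score = _gene_axis_score(df.columns)
        orientation = "genes_by_cells" if row_score > col_score else "cells_by_genes"
    if orientation == "genes_by_cells":
        df = df.T
    elif orientation != "cells_by_genes":
        raise FormatError(f"unknown orientation {orientation!r}")
    return _finalize(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
        None,
        None if label_key is None else label_key,
    )


def _read_mtx(path: Path, label_key) -> SingleCellDataset:
    """10x triplet dialect: matrix is genes x cells; features/barcodes TSVs sit
    beside it. A second barcodes column, when present, carries cell-type labels."""
    path = Path(path)
    folder = path.parent if path.is_file() else path
    mtx = path if path.is_file() else _first_existing(folder, ["matrix.mtx"])
    feats = _first_existing(folder, ["features.tsv", "genes.tsv"])
    bcs = _first_existing(folder, ["barcodes.tsv", "cells.tsv"])
    if mtx is None or feats is None or bcs is None:
        raise FormatError(f"MTX triplet incomplete in {folder}")
    M = scipy.io.mmread(mtx)
    fdf = pd.read_csv(feats, sep="\t", header=None)
    bdf = pd.read_csv(bcs, sep="\t", header=None)
    # 10x features.tsv: column 1 holds symbols when an id column is present
    sym_col = 1 if fdf.shape[1] > 1 else 0
    genes = [str(x) for x in fdf.iloc[:, sym_col]]
    cells = [str(x) for x in bdf.iloc[:, 0]]
    X = np.asarray(sp.csr_matrix(M).todense(), dtype=float).T  # -> cells x genes
    if X.shape != (len(cells), len(genes)):
        raise FormatError(
            f"matrix shape {M.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    labels = None
    if bdf.shape[1] > 1:
        labels = [str(x) for x in bdf.iloc[:, 1]]
    elif label_key is not None:
        raise FormatError(f"labels requested under {label_key!r} but barcodes file has one column")
    return _finalize(X, genes, cells, labels, None)


def _first_existing(folder: Path, names: list[str]) -> Path | None:
    for n in names:
        p = folder / n
        if p.exists():
            return p
    return None


def _read_h5ad(path: Path, label_key, layer: str | None) -> SingleCellDataset:
    adata = ad.read_h5ad(path)
    X = adata.layers[layer] if layer else adata.X
    X = np.asarray(sp.csr_matrix(X).todense(), dtype=float)
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise FormatError(f"label key {label_key!r} not in obs")
        labels = [str(x) for x in adata.obs[label_key]]
    elif "cell_type" in adata.obs:
        labels = [str(x) for x in adata.obs["cell_type"]]
    ds = _finalize(
        X, [str(v) for v in adata.var_names], [str(o) for o in adata.obs_names], labels, None
    )
    if "spatial" in adata.obsm:
        ds.coords = np.asarray(adata.obsm["spatial"], dtype=float)
    return ds


def read_expression(
    path,
    format: str | None = None,
    label_key: str | None = None,
    orientation: str = "auto",
    layer: str | None = None,
) -> SingleCellDataset:
    """Read an expression matrix into a :class:`SingleCellDataset`.

    Parameters
    ----------
    path
        File (``.h5ad``, ``.csv``/``.tsv``, ``.mtx``) or MTX triplet folder.
    format
        ``h5ad`` | ``mtx`` | ``csv``; inferred from the suffix when omitted.
    label_key
        Observation column holding cell-type labels (H5AD; default tries
        ``cell_type``). For MTX, labels come from a second barcodes column.
    orientation
        CSV only: ``cells_by_genes``, ``genes_by_cells`` or ``auto`` (score
        both axes for gene-symbol-likeness and transpose if rows win).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".h5ad": "h5ad",
            ".csv": "csv",
            ".tsv": "csv",
            ".txt": "csv",
            ".mtx": "mtx",
        }.get(suffix, "mtx" if path.is_dir() else None)
    if format == "h5ad":
        return _read_h5ad(path, label_key, layer)
    if format == "csv":
        return _read_csv(path, label_key, orientation)
    if format == "mtx":
        return _read_mtx(path, label_key)
    raise FormatError(f"unknown format {format!r}")


def write_expression(ds: SingleCellDataset, path, format: str | None = None) -> None:
    """Write a dataset as H5AD, CSV (cells x genes) or an MTX triplet folder."""
    path = Path(path)
    if format is None:
        format = {".h5ad": "h5ad", ".csv": "csv"}.get(path.suffix.lower(), "mtx")
    X = ds.dense_counts()
    if format == "h5ad":
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame({"cell_type": ds.cell_types}, index=ds.cell_ids),
            var=pd.DataFrame(index=ds.gene_symbols),
        )
        if ds.coords is not None:
            adata.obsm["spatial"] = ds.coords
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
    elif format == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(X, index=ds.cell_ids, columns=ds.gene_symbols).to_csv(path)
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(X.T))
        pd.DataFrame({"symbol": ds.gene_symbols}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame({"barcode": ds.cell_ids, "cell_type": ds.cell_types}).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        raise FormatError(f"unknown format {format!r}")
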