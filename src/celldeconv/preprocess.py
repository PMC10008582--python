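"""QC filtering, depth-log normalization, per-input model normalization, and
the training-time corruption operator.

Two normalizations live here and are deliberately distinct:

* :func:`depth_log_normalize` — corpus-level: scale each cell to a common
  target depth (10,000 counts) and log1p. Its output is the space in which
  pseudobulk mixtures are averaged.
* :func:`model_normalize` — per-input, at the model boundary: depth scale,
  log, z-score across genes, then min-max to [0, 1]. Because the z-score
  removes any linear rescaling, the result is invariant to the log base
  used upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InputError, QCError, SingleCellDataset


@dataclass
class QCParams:
    """Cell/gene quality-control thresholds.

    Cells with fewer than ``min_counts`` total counts, genes expressed in
    fewer than ``min_cells_per_gene`` cells, cells above ``max_mito_frac``
    mitochondrial read fraction, and cells whose ln(total counts) exceeds
    mean + ``depth_sd_mult`` * SD across cells are removed, in that order.
    """

    min_counts: int = 200
    min_cells_per_gene: int = 3
    max_mito_frac: float = 0.20
    depth_sd_mult: float = 2.0
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_counts <= 0 or self.min_cells_per_gene <= 0 or self.depth_sd_mult <= 0:
            raise InputError("QC thresholds must be positive")
        if not 0 < self.max_mito_frac <= 1:
            raise InputError("max_mito_frac must be in (0, 1]")


def qc_filter(ds: SingleCellDataset, qc: QCParams | None = None) -> SingleCellDataset:
    """Apply the four QC rules in order: low-count cells, rare genes, high-mito
    cells, depth outliers. Raises :class:`QCError` (with per-rule removal
    counts) if nothing survives."""
    qc = qc or QCParams()
    removed = {}
    X = ds.dense_counts()
    cells = np.arange(X.shape[0])

    totals = X.sum(axis=1)
    keep = totals >= qc.min_counts
    removed["low_count_cells"] = int((~keep).sum())
    X, cells = X[keep], cells[keep]

    n_expressing = (X > 0).sum(axis=0)
    gene_keep = n_expressing >= qc.min_cells_per_gene
    removed["rare_genes"] = int((~gene_keep).sum())
    X = X[:, gene_keep]
    genes = np.flatnonzero(gene_keep)

    mito = np.array([g.startswith(qc.mito_prefix.upper()) for g in
                     (ds.gene_symbols[j] for j in genes)])
    totals = X.sum(axis=1)
    if mito.any():
        frac = X[:, mito].sum(axis=1) / np.maximum(totals, 1)
    else:
        frac = np.zeros(X.shape[0])
    keep = frac <= qc.max_mito_frac
    removed["high_mito_cells"] = int((~keep).sum())
    X, cells = X[keep], cells[keep]

    if X.shape[0] > 0:
        totals = X.sum(axis=1)
        lt = np.log(np.maximum(totals, 1e-12))
        keep = lt <= lt.mean() + qc.depth_sd_mult * lt.std()
        removed["depth_outlier_cells"] = int((~keep).sum())
        cells = cells[keep]
    else:
        removed["depth_outlier_cells"] = 0

    if len(cells) == 0 or len(genes) == 0:
        raise QCError(f"QC removed everything: {removed}")
    return ds.subset_cells(cells).subset_genes(genes)


def depth_log_normalize(counts: np.ndarray, target: float = 10000.0) -> np.ndarray:
    """Scale each row to ``target`` total counts, then log1p.

    Depth-invariant: doubling every count in a row leaves the output
    unchanged. Rows with zero total raise an error naming the cell.
    """
    counts = np.asarray(counts, dtype=float)
    X = np.atleast_2d(counts)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise InputError(f"zero-total cells at rows {zero[:10].tolist()}")
    out = np.log1p(X * (target / totals)[:, None])
    return out if counts.ndim == 2 else out[0]


def normalize_dataset(ds: SingleCellDataset, target: float = 10000.0) -> SingleCellDataset:
    """Return a copy of ``ds`` whose matrix holds depth-log-normalized values."""
    out = ds.subset_cells(np.arange(ds.n_cells))
    out.counts = depth_log_normalize(ds.dense_counts(), target)
    out.normalized = True
    return out


def model_normalize(x: np.ndarray, already_log: bool = False) -> np.ndarray:
    """The model's 4-step per-input normalization.

    Raw path: counts -> scale to 10,000 -> log2(1 + x); log path skips both.
    Then per-vector z-score (population SD across genes) and min-max to
    [0, 1]. A constant vector (zero variance) maps to all-zeros, so empty
    inputs degrade gracefully. Accepts a vector or a sample x gene matrix
    (each row normalized independently).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite values in input")
    X = np.atleast_2d(x)
    if not already_log:
        if np.any(X < 0):
            raise InputError("raw counts must be non-negative")
        totals = X.sum(axis=1)
        scaled = np.where(totals[:, None] > 0, X * (10000.0 / np.maximum(totals, 1e-300))[:, None], 0.0)
        X = np.log2(1.0 + scaled)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population SD
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    lo = Z.min(axis=1, keepdims=True)
    rng_ = Z.max(axis=1, keepdims=True) - lo
    out = np.where(rng_ > 0, (Z - lo) / np.where(rng_ > 0, rng_, 1.0), 0.0)
    return out if x.ndim == 2 else out[0]


def corrupt(
    x: np.ndarray,
    noise_sigma: float = 0.05,
    dropout: float = 0.20,
    rng: np.random.Generator | None = None,
    rescale_survivors: bool = False,
) -> np.ndarray:
    """Training-time corruption: additive zero-mean Gaussian noise with SD
    ``noise_sigma`` on every entry, then each entry independently zeroed with
    probability ``dropout``. No inverse (1/(1-p)) rescale by default;
    ``rescale_survivors`` enables it for parity experiments."""
    if not 0 <= dropout < 1:
        raise InputError("dropout must be in [0, 1)")
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    out = x + (rng.normal(0.0, noise_sigma, size=x.shape) if noise_sigma > 0 else 0.0)
    if dropout > 0:
        mask = rng.random(size=x.shape) >= dropout
        out = out * mask
        if rescale_survivors:
            out = out / (1.0 - dropout)
    return out
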