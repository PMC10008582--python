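"""Scoring and benchmarking: Lin's concordance correlation coefficient,
per-type benchmark tables, sensitivity sweeps over mixture hyperparameters,
and spatial downsampling to pseudo-spots with known fractions.

Lin's CCC is used throughout because, unlike Pearson's r, it penalizes
location and scale shifts: CCC = 2 cov(x,y) / (var x + var y + (mean x -
mean y)^2), computed with population moments for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixer import MixerParams, build_training_set
from .network import DeconvModel, predict_fractions
from .preprocess import normalize_dataset
from .types import (
    CellTypeCatalog,
    ConfigError,
    DeconvolutionResult,
    InputError,
    SingleCellDataset,
)


def ccc(x: np.ndarray, y: np.ndarray, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient (population moments).

    A constant pair with equal means is the 0/0 limit and returns 0 by
    definition here; callers who need to distinguish degeneracy use
    :func:`benchmark`, which flags such columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ConfigError("ccc needs two equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in ccc input")
    ddof = 1 if sample_moments else 0
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    mg = x.mean() - y.mean()
    denom = vx + vy + mg * mg
    if denom == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (x.size - ddof)
    return float(2.0 * cov / denom)


@dataclass
class BenchmarkTable:
    """Per-cell-type CCC across samples plus summary mean."""

    table: pd.DataFrame  # columns: cell_type, ccc, degenerate
    mean_ccc: float
    condition: str = ""


def benchmark(
    pred: DeconvolutionResult, truth: np.ndarray,
    truth_catalog: CellTypeCatalog | None = None, condition: str = "",
) -> BenchmarkTable:
    """Per-type CCC between predicted and true fraction columns.

    Types are matched by name when ``truth_catalog`` is given (intersection,
    with others skipped), else positionally. Degenerate columns — zero
    variance on both sides — score 1 when the means also agree (perfect
    agreement) and 0 otherwise, and are flagged.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if truth.shape[0] != pred.fractions.shape[0]:
        raise ConfigError("pred and truth sample counts differ")
    if truth.shape[0] < 2:
        raise ConfigError("need >= 2 samples to benchmark")
    if truth_catalog is None:
        truth_catalog = pred.catalog
    common = [t for t in pred.catalog if t in truth_catalog.index]
    rows = []
    for t in common:
        p = pred.fractions[:, pred.catalog.index[t]]
        q = truth[:, truth_catalog.index[t]]
        degenerate = p.var() == 0 and q.var() == 0
        if degenerate:
            val = 1.0 if p.mean() == q.mean() else 0.0
        else:
            val = ccc(p, q)
        rows.append({"cell_type": t, "ccc": val, "degenerate": degenerate})
    df = pd.DataFrame(rows)
    return BenchmarkTable(table=df, mean_ccc=float(df["ccc"].mean()), condition=condition)


@dataclass
class SweepGrid:
    """One-axis sensitivity sweep; the other hyperparameters stay at the
    baseline (T=100 cells, N=5 types, 0% gene dropout)."""

    axis: str  # total_cells | n_types | gene_dropout
    values: list[float]
    replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis not in {"total_cells", "n_types", "gene_dropout"}:
            raise ConfigError(f"unknown sweep axis {self.axis!r}")
        for v in self.values:
            if self.axis == "gene_dropout" and not 0 <= v <= 1:
                raise ConfigError("gene_dropout values must lie in [0, 1]")
            if self.axis in {"total_cells", "n_types"} and (v < 1 or v != int(v)):
                raise ConfigError(f"{self.axis} values must be positive integers")


BASELINE = {"total_cells": 100, "n_types": 5, "gene_dropout": 0.0}


def apply_gene_dropout(
    X: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Randomly zero a fraction of each sample's expressed genes (input-stage
    dropout used in robustness sweeps)."""
    if not 0 <= frac <= 1:
        raise ConfigError("dropout fraction must be in [0, 1]")
    X = np.array(X, dtype=float, copy=True)
    for i in range(X.shape[0]):
        expressed = np.flatnonzero(X[i] > 0)
        k = int(round(frac * expressed.size))
        if k:
            X[i, rng.choice(expressed, size=k, replace=False)] = 0.0
    return X


def sensitivity_sweep(
    ds: SingleCellDataset,
    model: DeconvModel,
    grid: SweepGrid,
    baseline: dict | None = None,
) -> pd.DataFrame:
    """Mean CCC per grid value, perturbing one mixing hyperparameter at a
    time. ``ds`` must be depth-log-normalized and labeled."""
    if not ds.normalized:
        raise InputError("dataset must be depth-log-normalized")
    base = dict(BASELINE)
    base.update(baseline or {})
    rng = np.random.default_rng(grid.seed)
    catalog = ds.catalog()
    rows = []
    for v in grid.values:
        setting = dict(base)
        setting[grid.axis] = v
        T = int(setting["total_cells"])
        N = int(min(setting["n_types"], len(catalog)))
        mix_rng = np.random.default_rng(rng.integers(2**31))
        mp = MixerParams(T_range=(T, T), N_range=(N, N))
        mb = build_training_set(ds, grid.replicates, mp, rng=mix_rng, catalog=catalog)
        X = apply_gene_dropout(mb.X, float(setting["gene_dropout"]), mix_rng)
        pred = predict_fractions(model, X, already_log=True,
                                 gene_symbols=mb.gene_symbols)
        bt = benchmark(pred, mb.Y, truth_catalog=catalog)
        rows.append({"axis": grid.axis, "value": v, "mean_ccc": bt.mean_ccc,
                     "replicates": grid.replicates})
    return pd.DataFrame(rows)


def downsample_spatial(
    ds: SingleCellDataset, bin_size: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, CellTypeCatalog]:
    """Bin a high-resolution spatial dataset into pseudo-spots.

    Cells fall into square bins of side ``bin_size`` by floor(coord / bin);
    each non-empty bin becomes a spot whose expression is the mean of its
    members' depth-log-normalized profiles and whose truth row is the type
    count fractions. Returns (X spots x genes, Y spots x types, spot
    centers, catalog). Every cell lands in exactly one bin.
    """
    if ds.coords is None:
        raise InputError("dataset has no spatial coordinates")
    if bin_size <= 0:
        raise ConfigError("bin_size must be > 0")
    if ds.n_cells == 0:
        raise InputError("no cells in field")
    norm = ds if ds.normalized else normalize_dataset(ds)
    V = norm.dense_counts()
    catalog = ds.catalog()
    labels = np.array([catalog.index[t] for t in ds.cell_types])
    bins = np.floor(ds.coords / bin_size).astype(int)
    keys = [tuple(b) for b in bins]
    uniq = sorted(set(keys))
    X = np.zeros((len(uniq), ds.n_genes))
    Y = np.zeros((len(uniq), len(catalog)))
    centers = np.zeros((len(uniq), 2))
    key_idx = {k: i for i, k in enumerate(uniq)}
    counts = np.zeros(len(uniq), dtype=int)
    for c, k in enumerate(keys):
        i = key_idx[k]
        X[i] += V[c]
        Y[i, labels[c]] += 1
        counts[i] += 1
    X /= counts[:, None]
    Y /= counts[:, None]
    for k, i in key_idx.items():
        centers[i] = (np.array(k) + 0.5) * bin_size
    return X, Y, centers, catalog
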