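"""Core domain types shared across the deconvolution stack.

All containers are thin, validated dataclasses over NumPy arrays (dense or
CSR-sparse where noted). Contracts are value-level: two datasets with equal
values are interchangeable regardless of internal representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp


class CellDeconvError(Exception):
    """Base class for all package errors."""


class FormatError(CellDeconvError):
    pass


class OntologyError(CellDeconvError):
    pass


class CheckpointError(CellDeconvError):
    pass


class QCError(CellDeconvError):
    pass


class InputError(CellDeconvError):
    pass


class MixtureError(CellDeconvError):
    pass


class ConfigError(CellDeconvError):
    pass


class AlignmentError(CellDeconvError):
    pass


class TrainingError(CellDeconvError):
    pass


def _as_dense(m) -> np.ndarray:
    if sp.issparse(m):
        return np.asarray(m.todense())
    return np.asarray(m)


def canonical_gene_symbol(s: str) -> str:
    """Canonical gene identity: stripped, uppercased symbol string."""
    return str(s).strip().upper()


@dataclass
class SingleCellDataset:
    """A labeled cell x gene count (or normalized expression) matrix.

    ``counts`` is raw transcript counts on construction from a file/generator;
    after :func:`celldeconv.preprocess.depth_log_normalize` the same container
    carries log-normalized values (tracked by ``normalized``).
    """

    counts: np.ndarray | sp.spmatrix
    gene_symbols: list[str]
    cell_types: list[str]
    cell_ids: list[str]
    coords: Optional[np.ndarray] = None  # (n_cells, 2), spatial fixtures only
    normalized: bool = False

    def __post_init__(self) -> None:
        n_cells, n_genes = self.shape
        if len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} columns"
            )
        if len(self.cell_types) != n_cells:
            raise FormatError(
                f"{len(self.cell_types)} cell-type labels for {n_cells} cells"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(f"{len(self.cell_ids)} cell ids for {n_cells} cells")
        syms = [canonical_gene_symbol(s) for s in self.gene_symbols]
        if len(set(syms)) != len(syms):
            raise FormatError("gene symbols not unique after uppercase normalization")
        self.gene_symbols = syms
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if not np.all(np.isfinite(data)):
            raise FormatError("non-finite values in expression matrix")
        if data.size and data.min() < 0:
            raise FormatError("negative values in expression matrix")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n_cells, 2):
                raise FormatError("coords must be (n_cells, 2)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.shape[0]

    @property
    def n_genes(self) -> int:
        return self.shape[1]

    def dense_counts(self) -> np.ndarray:
        return _as_dense(self.counts).astype(float)

    def catalog(self) -> "CellTypeCatalog":
        return CellTypeCatalog(sorted(set(self.cell_types)))

    def subset_cells(self, idx: Sequence[int] | np.ndarray) -> "SingleCellDataset":
        idx = np.asarray(idx)
        return SingleCellDataset(
            counts=self.counts[idx],
            gene_symbols=list(self.gene_symbols),
            cell_types=[self.cell_types[i] for i in idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            coords=None if self.coords is None else self.coords[idx],
            normalized=self.normalized,
        )

    def subset_genes(self, idx: Sequence[int] | np.ndarray) -> "SingleCellDataset":
        idx = np.asarray(idx)
        return SingleCellDataset(
            counts=self.counts[:, idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
            cell_types=list(self.cell_types),
            cell_ids=list(self.cell_ids),
            coords=self.coords,
            normalized=self.normalized,
        )


@dataclass
class CellTypeCatalog:
    """Ordered, unique cell-type names; the model's output axis."""

    type_names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.type_names)) != len(self.type_names):
            raise ConfigError("duplicate names in cell-type catalog")
        self.index = {name: i for i, name in enumerate(self.type_names)}

    def __len__(self) -> int:
        return len(self.type_names)

    def __iter__(self):
        return iter(self.type_names)

    def __eq__(self, other) -> bool:
        return isinstance(other, CellTypeCatalog) and self.type_names == other.type_names


@dataclass
class MixtureSpec:
    """Sampling plan for one pseudobulk mixture.

    T total cells, N unique types, the chosen type names, and the drawn
    fraction ratios F (non-negative, summing to 1).
    """

    T: int
    N: int
    types: list[str]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.T < 1:
            raise ConfigError("T must be >= 1")
        if self.N < 1 or self.N != len(self.types) or self.N != len(self.F):
            raise ConfigError("N must equal len(types) == len(F) and be >= 1")
        if np.any(self.F < 0) or abs(self.F.sum() - 1.0) > 1e-12:
            raise ConfigError("F must be non-negative and sum to 1 within 1e-12")


@dataclass
class MixtureBatch:
    """Pseudobulk mixtures X with realized ground-truth fractions Y."""

    X: np.ndarray  # (n_mixtures, n_genes), mean log-normalized space
    Y: np.ndarray  # (n_mixtures, n_catalog), rows on the simplex
    specs: list[MixtureSpec]
    catalog: CellTypeCatalog
    gene_symbols: list[str] = field(default_factory=list)
    cell_indices: list[np.ndarray] = field(default_factory=list)  # provenance

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ConfigError("X and Y row counts differ")
        if not np.all(np.isfinite(self.X)):
            raise ConfigError("non-finite mixture expression")
        if np.any(self.Y < 0) or np.any(np.abs(self.Y.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigError("Y rows must be non-negative and sum to 1 within 1e-9")

    @property
    def n_mixtures(self) -> int:
        return self.X.shape[0]


@dataclass
class DeconvolutionResult:
    """Predicted cell-type fractions per sample, rows on the simplex."""

    fractions: np.ndarray  # (n_samples, n_types)
    catalog: CellTypeCatalog
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        n, k = self.fractions.shape
        if k != len(self.catalog):
            raise ConfigError("fraction width does not match catalog")
        if len(self.sample_ids) != n:
            raise ConfigError("sample_ids length mismatch")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ConfigError("fractions must lie in [0, 1]")
        if np.any(np.abs(self.fractions.sum(axis=1) - 1.0) > 1e-5):
            raise ConfigError("fraction rows must sum to 1 within 1e-5")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.fractions, index=self.sample_ids, columns=self.catalog.type_names
        )
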