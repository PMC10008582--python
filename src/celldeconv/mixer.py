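"""Pseudobulk mixture simulation with known cell-type fractions.

A mixture is drawn in four steps: total cell count T (uniform over
``T_range``), number of unique types N (uniform over ``N_range``, clipped to
the catalog), the N type names (uniform without replacement over the
catalog — deliberately not frequency-weighted, which oversamples rare
classes), and fraction ratios F (flat Dirichlet, summing to 1). Realizing a
mixture apportions T x F to integer per-type cell counts by largest
remainder, samples cells without replacement within each type (taking the
whole pool if exhausted), and averages their depth-log-normalized profiles.
The ground-truth label is the realized fraction vector — the composition of
the cells actually averaged — not the drawn F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    CellTypeCatalog,
    ConfigError,
    MixtureBatch,
    MixtureError,
    MixtureSpec,
    SingleCellDataset,
)


@dataclass
class MixerParams:
    T_range: tuple[int, int] = (1, 10000)
    N_range: tuple[int, int] = (1, 32)
    fraction_law: str = "flat_dirichlet"
    linear_space: bool = False  # average expm1 profiles instead of log profiles
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.T_range, self.N_range):
            if lo < 1 or lo > hi:
                raise ConfigError("ranges must be positive and ordered")
        if self.fraction_law != "flat_dirichlet":
            raise ConfigError(f"unknown fraction law {self.fraction_law!r}")


def draw_mixture_spec(
    catalog: CellTypeCatalog, p: MixerParams, rng: np.random.Generator
) -> MixtureSpec:
    """Draw (T, N, types, F) for one mixture."""
    if len(catalog) == 0:
        raise ConfigError("empty catalog")
    T = int(rng.integers(p.T_range[0], p.T_range[1] + 1))
    n_hi = min(p.N_range[1], len(catalog))
    n_lo = min(p.N_range[0], n_hi)
    N = int(rng.integers(n_lo, n_hi + 1))
    idx = rng.choice(len(catalog), size=N, replace=False)
    idx.sort()  # catalog order; keeps apportionment tie-breaks canonical
    types = [catalog.type_names[i] for i in idx]
    F = rng.dirichlet(np.ones(N))
    F = F / F.sum()
    return MixtureSpec(T=T, N=N, types=types, F=F)


def apportion(T: int, F: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of T x F to integers summing to T.

    Ties in the fractional remainders are broken by position (catalog order).
    """
    F = np.asarray(F, dtype=float)
    exact = T * F
    base = np.floor(exact).astype(int)
    short = T - base.sum()
    if short > 0:
        remainder = exact - base
        # stable sort descending by remainder; ties resolve to lower index
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    return base


def realize_mixture(
    ds: SingleCellDataset,
    spec: MixtureSpec,
    rng: np.random.Generator,
    type_index: dict[str, np.ndarray] | None = None,
    linear_space: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample cells for ``spec`` and average their profiles.

    Returns (x, y, cell_idx): the mean profile, the realized per-spec-type
    fraction vector, and the selected cell row indices. ``ds`` must hold
    depth-log-normalized values. If a type's pool is smaller than its target
    count, the whole pool is used without duplication and y reflects that.
    """
    if not ds.normalized:
        raise MixtureError("dataset must be depth-log-normalized before mixing")
    if type_index is None:
        type_index = index_types(ds)
    targets = apportion(spec.T, spec.F)
    chosen: list[np.ndarray] = []
    realized = np.zeros(spec.N)
    for k, t in enumerate(spec.types):
        pool = type_index.get(t)
        if pool is None:
            raise MixtureError(f"type {t!r} absent from dataset")
        take = min(targets[k], len(pool))
        if take > 0:
            chosen.append(rng.choice(pool, size=take, replace=False))
            realized[k] = take
    if not chosen:
        raise MixtureError("no cells selected (all pools empty or all targets 0)")
    cell_idx = np.concatenate(chosen)
    y = realized / realized.sum()
    profiles = ds.counts[cell_idx]
    if hasattr(profiles, "toarray"):
        profiles = profiles.toarray()
    profiles = np.asarray(profiles, dtype=float)
    if linear_space:
        x = np.log1p(np.expm1(profiles).mean(axis=0))
    else:
        x = profiles.mean(axis=0)
    return x, y, cell_idx


def index_types(ds: SingleCellDataset) -> dict[str, np.ndarray]:
    """Pre-index cell row locations per type (built once, reused per batch)."""
    labels = np.asarray(ds.cell_types)
    return {t: np.flatnonzero(labels == t) for t in np.unique(labels)}


def build_training_set(
    ds: SingleCellDataset,
    n_mixtures: int,
    p: MixerParams | None = None,
    rng: np.random.Generator | None = None,
    catalog: CellTypeCatalog | None = None,
) -> MixtureBatch:
    """Generate ``n_mixtures`` pseudobulk mixtures with realized truth rows."""
    if n_mixtures <= 0:
        raise ConfigError("n_mixtures must be positive")
    p = p or MixerParams()
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    catalog = catalog or ds.catalog()
    tix = index_types(ds)
    X = np.zeros((n_mixtures, ds.n_genes))
    Y = np.zeros((n_mixtures, len(catalog)))
    specs: list[MixtureSpec] = []
    cell_indices: list[np.ndarray] = []
    for i in range(n_mixtures):
        spec = draw_mixture_spec(catalog, p, rng)
        x, y, idx = realize_mixture(
            ds, spec, rng, type_index=tix, linear_space=p.linear_space
        )
        X[i] = x
        for k, t in enumerate(spec.types):
            Y[i, catalog.index[t]] = y[k]
        specs.append(spec)
        cell_indices.append(idx)
    return MixtureBatch(
        X=X,
        Y=Y,
        specs=specs,
        catalog=catalog,
        gene_symbols=list(ds.gene_symbols),
        cell_indices=cell_indices,
    )
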