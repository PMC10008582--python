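"""Reference-guided transfer-learning deconvolution.

Pipeline: average a labeled reference into per-type mean signatures; push
signatures and mixtures through the trained network and take the two middle
hidden layers as universal cell-state embeddings; per feature block
(embedding layers, plus highly variable genes), reduce the reference with
non-negative matrix factorization, project the mixtures onto the fixed
dictionary by non-negative least squares, and align the two batches of
components; concatenate the aligned components and regress each mixture's
component vector on the reference component matrix with a bagged linear
nu-SVR ensemble whose averaged primal coefficients — clipped at zero and
renormalized — are the cell-type fractions. The regression orientation is
signature-based (components are observations, cell types are predictors),
the standard support-vector deconvolution setup.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVR

from .network import DeconvModel, extract_embeddings
from .types import (
    CellTypeCatalog,
    ConfigError,
    DeconvolutionResult,
    InputError,
    SingleCellDataset,
)

log = logging.getLogger(__name__)


@dataclass
class ReferenceSignature:
    """Per-type mean log-normalized expression (types x genes)."""

    type_names: list[str]
    matrix: np.ndarray
    gene_symbols: list[str]


@dataclass
class SelectParams:
    """Transfer-model settings. ``n_components`` defaults to the number of
    reference types (one factor per state); ``use_blocks`` selects the
    feature sources (network embeddings, genes, or both)."""

    n_components: int | None = None
    n_hvg: int = 2000
    n_bags: int = 48
    nu: float = 0.5
    svr_C: float = 10.0
    svr_max_iter: int = 2000
    use_blocks: str = "both"  # embeddings | genes | both
    shrink_combat: bool = False  # empirical-Bayes ComBat instead of exact location-scale
    clip_mode: str = "zero"  # zero | shift (shift block minimum to 0 before NMF)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components is not None and self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.n_bags < 1:
            raise ConfigError("n_bags must be >= 1")
        if not 0 < self.nu <= 1:
            raise ConfigError("nu must be in (0, 1]")
        if self.svr_C <= 0:
            raise ConfigError("svr_C must be > 0")
        if self.use_blocks not in {"embeddings", "genes", "both"}:
            raise ConfigError(f"unknown use_blocks {self.use_blocks!r}")


def build_signature(reference: SingleCellDataset) -> ReferenceSignature:
    """Average reference cells into one row per label (label-sorted order)."""
    if not reference.normalized:
        raise InputError("reference must be depth-log-normalized")
    labels = sorted(set(reference.cell_types))
    if len(labels) < 2:
        raise InputError("deconvolution needs a reference with >= 2 cell states")
    X = reference.dense_counts()
    arr = np.asarray(reference.cell_types)
    rows = np.vstack([X[arr == t].mean(axis=0) for t in labels])
    return ReferenceSignature(labels, rows, list(reference.gene_symbols))


def select_hvg(signature: ReferenceSignature, n: int) -> np.ndarray:
    """Top-n gene indices by across-type variance of the signature rows
    (population variance; ties broken by symbol order)."""
    var = signature.matrix.var(axis=0)
    n_genes = var.size
    if n > n_genes:
        log.warning("n_hvg=%d clipped to %d genes", n, n_genes)
        n = n_genes
    # sort by (-variance, symbol) for deterministic ties
    order = sorted(range(n_genes), key=lambda j: (-var[j], signature.gene_symbols[j]))
    return np.array(sorted(order[:n]))


def _clip_block(B: np.ndarray, mode: str) -> np.ndarray:
    if mode == "shift":
        return B - min(B.min(), 0.0)
    return np.clip(B, 0.0, None)


def factorize_align(
    ref_block: np.ndarray,
    mix_block: np.ndarray,
    k: int,
    seed: int = 0,
    clip_mode: str = "zero",
    shrink_combat: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """NMF the reference block, project mixtures on the fixed dictionary,
    then batch-align the two component sets.

    Negative entries (possible for ELU embeddings) are clipped to zero before
    factorization. NMF uses deterministic NNDSVD-style initialization on the
    reference; each mixture row is then solved by non-negative least squares
    against the dictionary. Alignment is a parametric location-scale
    adjustment per component with batch in {reference, mixture} and no
    covariates: each batch is standardized on its own moments and restored
    to the pooled moments, making the per-component batch means agree
    exactly. ``shrink_combat=True`` instead applies empirical-Bayes ComBat
    (scanpy), which shrinks per-component batch effects toward each other.
    """
    ref_block = np.atleast_2d(np.asarray(ref_block, dtype=float))
    mix_block = np.atleast_2d(np.asarray(mix_block, dtype=float))
    if ref_block.shape[1] != mix_block.shape[1]:
        raise ConfigError("reference and mixture blocks differ in width")
    d = ref_block.shape[1]
    if k > min(d, ref_block.shape[0]):
        raise ConfigError(f"k={k} exceeds feasible rank of a {ref_block.shape} block")
    R = _clip_block(ref_block, clip_mode)
    M = _clip_block(mix_block, clip_mode)
    if not R.any():
        raise ConfigError("reference block is all zeros after clipping")
    nmf = NMF(
        n_components=k,
        init="nndsvda",
        solver="cd",
        max_iter=2000,
        random_state=seed,
        tol=1e-6,
    )
    W_ref = nmf.fit_transform(R)
    H = nmf.components_  # (k, d)
    W_mix = np.vstack([nnls(H.T, M[i])[0] for i in range(M.shape[0])])

    if shrink_combat:
        W_ref_a, W_mix_a = _combat_eb(W_ref, W_mix)
    else:
        W_ref_a, W_mix_a = _location_scale_align(W_ref, W_mix)
    return W_ref_a, W_mix_a


def _location_scale_align(A: np.ndarray, B: np.ndarray):
    """Per-component two-batch standardization to pooled moments."""
    stacked = np.vstack([A, B])
    alpha = stacked.mean(axis=0)
    sigma = stacked.std(axis=0)

    def adjust(X):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return alpha + sigma * z

    return adjust(A), adjust(B)


def _combat_eb(A: np.ndarray, B: np.ndarray):
    import anndata as ad
    import pandas as pd
    import scanpy as sc

    n_a, n_b = A.shape[0], B.shape[0]
    adata = ad.AnnData(
        X=np.vstack([A, B]),
        obs=pd.DataFrame(
            {"batch": ["reference"] * n_a + ["mixture"] * n_b},
            index=[f"r{i}" for i in range(n_a)] + [f"m{i}" for i in range(n_b)],
        ),
    )
    sc.pp.combat(adata, key="batch")
    X = np.asarray(adata.X)
    return X[:n_a], X[n_a:]


def svr_deconvolve(
    mix_components: np.ndarray,
    ref_components: np.ndarray,
    p: SelectParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bagged linear nu-SVR regression of each mixture on the reference.

    Per sample, the design matrix is the reference component matrix
    transposed (observations = components, predictors = cell types) and the
    response is the sample's component vector; both are standardized by the
    design's pooled moments before fitting, so regularization strength is
    scale-free. ``n_bags`` estimators (NuSVR, linear kernel, C=``svr_C`` —
    large by default: with about as many observations as predictors a
    near-interpolating fit is wanted) are each fit on a bootstrap of the
    component observations; primal coefficients are averaged, clipped at
    zero, and renormalized to the simplex (uniform fallback when every
    coefficient is non-positive).
    """
    rng = rng or np.random.default_rng(p.seed)
    mix_components = np.atleast_2d(mix_components)
    ref_components = np.atleast_2d(ref_components)
    k_total, n_types = ref_components.shape[1], ref_components.shape[0]
    if mix_components.shape[1] != k_total:
        raise ConfigError("component width mismatch")
    design = ref_components.T  # (k_total, n_types)
    mu, sd = design.mean(), design.std()
    sd = sd if sd > 0 else 1.0
    D = (design - mu) / sd
    out = np.zeros((mix_components.shape[0], n_types))
    def _fit(rows, y):
        svr = NuSVR(kernel="linear", nu=p.nu, C=p.svr_C, max_iter=p.svr_max_iter)
        with warnings.catch_warnings():
            # the solver is deliberately iteration-capped: bagged coefficient
            # averages are insensitive to the last digits of each fit
            warnings.simplefilter("ignore", ConvergenceWarning)
            svr.fit(D[rows], y[rows])
        c = svr.coef_.ravel()
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coefficients")
        return c

    all_rows = np.arange(k_total)
    for i in range(mix_components.shape[0]):
        y = (mix_components[i] - mu) / sd
        coefs = np.zeros(n_types)
        fitted = 0
        for _ in range(p.n_bags):
            # a bootstrap can be numerically degenerate (near-duplicate rows);
            # redraw a couple of times, then fall back to the full design
            for attempt in range(3):
                rows = rng.integers(0, k_total, size=k_total)
                try:
                    coefs += _fit(rows, y)
                    fitted += 1
                    break
                except ValueError:
                    continue
            else:
                try:
                    coefs += _fit(all_rows, y)
                    fitted += 1
                except ValueError:
                    pass
        if fitted == 0:
            raise InputError(f"no SVR bag converged for sample {i}")
        coefs /= fitted
        coefs = np.clip(coefs, 0.0, None)
        s = coefs.sum()
        out[i] = coefs / s if s > 0 else np.full(n_types, 1.0 / n_types)
    return out


def run_select(
    model: DeconvModel,
    mixtures: np.ndarray,
    reference: SingleCellDataset,
    p: SelectParams | None = None,
    mixture_gene_symbols: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> DeconvolutionResult:
    """Full transfer pipeline; result columns are the reference labels.

    ``mixtures`` rows are expression profiles in the reference's gene
    namespace (depth-log-normalized space), or in their own namespace when
    ``mixture_gene_symbols`` is given.
    """
    p = p or SelectParams()
    sig = build_signature(reference)
    mixtures = np.atleast_2d(np.asarray(mixtures, dtype=float))
    genes = mixture_gene_symbols or sig.gene_symbols
    if len(genes) != mixtures.shape[1]:
        raise ConfigError("mixture gene symbols do not match matrix width")
    if mixture_gene_symbols is not None and list(genes) != list(sig.gene_symbols):
        # bring mixtures into the reference namespace (shared-symbol columns)
        pos = {g: j for j, g in enumerate(genes)}
        aligned = np.zeros((mixtures.shape[0], len(sig.gene_symbols)))
        for j, g in enumerate(sig.gene_symbols):
            if g in pos:
                aligned[:, j] = mixtures[:, pos[g]]
        mixtures = aligned

    k = p.n_components or len(sig.type_names)
    seeds = np.random.SeedSequence(p.seed).spawn(4)
    blocks_ref: list[np.ndarray] = []
    blocks_mix: list[np.ndarray] = []

    if p.use_blocks in {"embeddings", "both"}:
        ref_embs = extract_embeddings(
            model, sig.matrix, gene_symbols=sig.gene_symbols
        )
        mix_embs = extract_embeddings(model, mixtures, gene_symbols=sig.gene_symbols)
        for bi, (re_, me) in enumerate(zip(ref_embs, mix_embs)):
            r, m = factorize_align(
                re_, me, k=min(k, min(re_.shape)), seed=int(seeds[bi].generate_state(1)[0] % 2**31),
                clip_mode=p.clip_mode, shrink_combat=p.shrink_combat,
            )
            blocks_ref.append(r)
            blocks_mix.append(m)
    if p.use_blocks in {"genes", "both"}:
        hvg = select_hvg(sig, p.n_hvg)
        r, m = factorize_align(
            sig.matrix[:, hvg], mixtures[:, hvg], k=min(k, len(hvg), len(sig.type_names)),
            seed=int(seeds[2].generate_state(1)[0] % 2**31),
            clip_mode=p.clip_mode, shrink_combat=p.shrink_combat,
        )
        blocks_ref.append(r)
        blocks_mix.append(m)

    ref_components = np.hstack(blocks_ref)
    mix_components = np.hstack(blocks_mix)
    if ref_components.shape[1] < len(sig.type_names):
        raise ConfigError("fewer total components than reference cell types")
    svr_rng = np.random.default_rng(int(seeds[3].generate_state(1)[0] % 2**31))
    fractions = svr_deconvolve(mix_components, ref_components, p, rng=svr_rng)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(fractions.shape[0])]
    return DeconvolutionResult(
        fractions=fractions,
        catalog=CellTypeCatalog(sig.type_names),
        sample_ids=sample_ids,
    )
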