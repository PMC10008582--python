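"""Shared fixtures: a planted-marker corpus, its normalized form, and a
network trained at the standard recovery conditions (5,000 mixtures of 1 to
1,000 cells drawn from an 8-type, 200-gene corpus, seed 0). Training takes a
few seconds, so the trained model is session-scoped and reused by the
network, attribution, transfer and acceptance tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import celldeconv as cd

warnings.filterwarnings("ignore", message=".*force_all_finite.*")


@pytest.fixture(scope="session")
def corpus() -> cd.SingleCellDataset:
    return cd.make_corpus(cd.CorpusConfig(seed=0))


@pytest.fixture(scope="session")
def norm_corpus(corpus) -> cd.SingleCellDataset:
    return cd.normalize_dataset(corpus)


@pytest.fixture(scope="session")
def catalog(norm_corpus) -> cd.CellTypeCatalog:
    return norm_corpus.catalog()


@pytest.fixture(scope="session")
def training_batch(norm_corpus) -> cd.MixtureBatch:
    return cd.build_training_set(
        norm_corpus, 5000, cd.MixerParams(T_range=(1, 1000), N_range=(1, 8), seed=0)
    )


@pytest.fixture(scope="session")
def tiny_config() -> cd.ModelConfig:
    return cd.ModelConfig(n_genes=200, hidden=(256, 128, 64, 32), n_outputs=8, seed=0)


@pytest.fixture(scope="session")
def trained_model(tiny_config, training_batch, norm_corpus) -> cd.DeconvModel:
    model = cd.build_model(tiny_config, training_batch.catalog, norm_corpus.gene_symbols)
    model, _ = cd.train(model, training_batch, cd.TrainParams(seed=0))
    return model


@pytest.fixture(scope="session")
def heldout_batch(norm_corpus) -> cd.MixtureBatch:
    """Mixtures the trained model never saw (fresh mixer stream)."""
    return cd.build_training_set(
        norm_corpus, 300, cd.MixerParams(T_range=(1, 1000), N_range=(1, 8), seed=123)
    )


@pytest.fixture(scope="session")
def reference_and_mixtures(norm_corpus):
    """Disjoint cell split of the corpus: one half averaged as the transfer
    reference, mixtures drawn from the other half."""
    rng = np.random.default_rng(42)
    perm = rng.permutation(norm_corpus.n_cells)
    half = norm_corpus.n_cells // 2
    ref = norm_corpus.subset_cells(perm[:half])
    mix_src = norm_corpus.subset_cells(perm[half:])
    mixtures = cd.build_training_set(
        mix_src, 200, cd.MixerParams(T_range=(100, 100), N_range=(2, 8), seed=7)
    )
    return ref, mixtures


@pytest.fixture(scope="session")
def spatial_ds() -> cd.SingleCellDataset:
    cfg = cd.SpatialConfig(
        n_types=4, n_genes=100, cells_per_type=10, markers_per_type=5,
        field_size=(300.0, 300.0), n_niches=3, cell_spacing=10.0, seed=1,
    )
    return cd.make_spatial(cfg)
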