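"""Network contracts: parameter counting, the masked loss, the training
schedule, prediction simplex, gene alignment, embeddings."""

import numpy as np
import pytest

import celldeconv as cd
from celldeconv.network import (
    ModelConfig,
    TrainParams,
    align_genes,
    build_model,
    extract_embeddings,
    parameter_count,
    predict_fractions,
    sparse_mse,
    train,
)
from celldeconv.types import AlignmentError, CellTypeCatalog, ConfigError, TrainingError


@pytest.mark.parametrize(
    "cfg,expected",
    [
        (ModelConfig(n_genes=28867, hidden=(8192, 4096, 2048, 1024), n_outputs=840),
         281_395_016),
        (ModelConfig(n_genes=200, hidden=(256, 128, 64, 32), n_outputs=8), 94_952),
    ],
)
def test_parameter_count_closed_form(cfg, expected):
    assert parameter_count(cfg) == expected


def test_parameter_count_matches_allocated_weights(tiny_config, catalog):
    m = build_model(tiny_config, catalog)
    allocated = sum(W.size + b.size for W, b in zip(m.W, m.b))
    assert allocated == m.n_parameters


def test_config_validation():
    with pytest.raises(ConfigError):
        ModelConfig(n_genes=10, hidden=(16,), n_outputs=2)  # needs two hidden layers
    with pytest.raises(ConfigError):
        ModelConfig(n_genes=0, hidden=(4, 4), n_outputs=2)


class TestSparseMSE:
    def test_worked_example(self):
        val = sparse_mse(np.array([[0.5, 0.5, 0.0]]), np.array([[0.4, 0.4, 0.2]]))
        assert abs(val - 0.01) < 1e-15

    def test_zero_on_perfect_prediction(self):
        y = np.random.default_rng(0).dirichlet(np.ones(5), size=10)
        assert sparse_mse(y, y) == 0.0

    def test_equals_plain_mse_on_dense_truth(self):
        rng = np.random.default_rng(1)
        y = rng.dirichlet(np.full(4, 5.0), size=20)  # all entries > 0
        p = rng.dirichlet(np.ones(4), size=20)
        assert abs(sparse_mse(y, p) - np.mean((y - p) ** 2)) < 1e-12

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            y = rng.dirichlet(np.ones(6), size=8)
            y[y < 0.15] = 0.0
            y = y / y.sum(axis=1, keepdims=True)
            p = rng.dirichlet(np.ones(6), size=8)
            acc = []
            for i in range(8):
                errs = [(p[i, j] - y[i, j]) ** 2 for j in range(6) if y[i, j] > 0]
                acc.append(sum(errs) / len(errs))
            assert abs(sparse_mse(y, p) - np.mean(acc)) < 1e-12

    def test_all_zero_truth_row_rejected(self):
        with pytest.raises(TrainingError):
            sparse_mse(np.zeros((1, 3)), np.full((1, 3), 1 / 3))


class TestPrediction:
    def test_simplex_conservation(self, trained_model):
        rng = np.random.default_rng(0)
        X = rng.random((50, 200)) * 8
        res = predict_fractions(trained_model, X, already_log=True)
        assert (res.fractions >= 0).all()
        np.testing.assert_allclose(res.fractions.sum(axis=1), 1.0, atol=1e-5)

    def test_inference_deterministic(self, trained_model, heldout_batch):
        X = np.vstack([heldout_batch.X[:3], heldout_batch.X[:3]])
        res = predict_fractions(trained_model, X, already_log=True)
        np.testing.assert_array_equal(res.fractions[:3], res.fractions[3:])

    def test_gene_permutation_invariance(self, trained_model, heldout_batch):
        """Shuffling columns together with their symbols changes nothing."""
        rng = np.random.default_rng(1)
        perm = rng.permutation(200)
        X = heldout_batch.X[:5]
        base = predict_fractions(trained_model, X, already_log=True).fractions
        shuffled = predict_fractions(
            trained_model, X[:, perm], already_log=True,
            gene_symbols=[trained_model.gene_symbols[j] for j in perm],
        ).fractions
        np.testing.assert_allclose(base, shuffled, atol=1e-12)

    def test_all_zero_row_is_valid(self, trained_model):
        res = predict_fractions(trained_model, np.zeros((1, 200)), already_log=True)
        np.testing.assert_allclose(res.fractions.sum(), 1.0, atol=1e-5)

    def test_low_overlap_rejected(self, trained_model):
        with pytest.raises(AlignmentError):
            align_genes(trained_model, np.ones((1, 5)),
                        ["NOPE1", "NOPE2", "NOPE3", "NOPE4", "NOPE5"])

    def test_missing_genes_zero_filled_and_unknown_dropped(self, trained_model):
        symbols = [f"GENE{j}" for j in range(30)] + ["XWZ"]
        X = align_genes(trained_model, np.ones((2, 31)), symbols)
        assert X.shape == (2, 200)
        assert X[:, :30].sum() == 60 and X.sum() == 60  # XWZ dropped, rest zero


class TestEmbeddings:
    def test_middle_two_rule(self, trained_model, heldout_batch):
        embs = extract_embeddings(trained_model, heldout_batch.X[:4])
        assert [e.shape[1] for e in embs] == [128, 64]

    def test_explicit_layers_and_bounds(self, trained_model, heldout_batch):
        embs = extract_embeddings(trained_model, heldout_batch.X[:2], layers=(0, 3))
        assert [e.shape[1] for e in embs] == [256, 32]
        with pytest.raises(ConfigError):
            extract_embeddings(trained_model, heldout_batch.X[:2], layers=(4,))

    def test_deterministic(self, trained_model, heldout_batch):
        a = extract_embeddings(trained_model, heldout_batch.X[:3])
        b = extract_embeddings(trained_model, heldout_batch.X[:3])
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestTrainingSchedule:
    @pytest.fixture(scope="class")
    def small_batch(self, norm_corpus):
        return cd.build_training_set(
            norm_corpus, 80, cd.MixerParams(T_range=(1, 200), N_range=(1, 8), seed=3)
        )

    def _quiet_config(self):
        return ModelConfig(n_genes=200, hidden=(256, 128, 64, 32), n_outputs=8,
                           noise_sigma=0.0, input_dropout=0.0, seed=0)

    def test_overfit_capacity(self, small_batch, norm_corpus):
        """Corruption-free training on 64 fixed mixtures drives the masked
        loss below 1e-3 (the stack has enough capacity)."""
        m = build_model(self._quiet_config(), small_batch.catalog,
                        norm_corpus.gene_symbols)
        m, hist = train(m, small_batch, TrainParams(
            batch_size=32, max_epochs=200, lr=1e-3, early_stop_patience=1000,
            lr_drop_patience=1000, seed=0))
        assert hist.train_loss[-1] < 1e-3

    def test_early_stop_on_constant_loss(self, small_batch, norm_corpus):
        """With lr=0 the loss never improves; early stopping fires at
        patience + 1 epochs."""
        m = build_model(self._quiet_config(), small_batch.catalog,
                        norm_corpus.gene_symbols)
        m, hist = train(m, small_batch, TrainParams(
            batch_size=32, max_epochs=50, lr=0.0, early_stop_patience=4, seed=0))
        assert hist.stop_reason == "early_stop"
        assert hist.stopped_epoch == 5

    def test_lr_halves_on_plateau(self, small_batch, norm_corpus):
        """When no epoch counts as an improvement, the LR halves every
        patience epochs."""
        m = build_model(self._quiet_config(), small_batch.catalog,
                        norm_corpus.gene_symbols)
        m, hist = train(m, small_batch, TrainParams(
            batch_size=32, max_epochs=12, lr=1e-4, lr_drop_delta=1e9,
            lr_drop_patience=5, early_stop_patience=100, early_stop_delta=-1e9,
            seed=0))
        assert hist.lr_trace[5] == pytest.approx(1e-4)
        assert hist.lr_trace[6] == pytest.approx(5e-5)
        assert hist.lr_trace[11] == pytest.approx(2.5e-5)

    def test_validation_recorded_on_interval(self, small_batch, norm_corpus):
        m = build_model(self._quiet_config(), small_batch.catalog,
                        norm_corpus.gene_symbols)
        m, hist = train(m, small_batch, TrainParams(
            batch_size=32, max_epochs=10, eval_interval=5,
            early_stop_patience=100, seed=0))
        assert [e for e, _ in hist.val_loss] == [5, 10]

    def test_too_few_mixtures_rejected(self, small_batch, norm_corpus):
        m = build_model(self._quiet_config(), small_batch.catalog,
                        norm_corpus.gene_symbols)
        with pytest.raises(ConfigError):
            train(m, small_batch, TrainParams(batch_size=256))
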