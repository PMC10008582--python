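"""The deconvolution network.

A fully connected stack — ``n_genes -> hidden[0] -> ... -> hidden[-1] ->
n_outputs`` — with ELU activations on the hidden layers and a softmax head,
so every prediction row is a valid fraction vector on the simplex. Training
minimizes a masked ("sparse") MSE that only scores cell types truly present
in each mixture: with a large catalog almost all true fractions are zero,
and unmasked MSE would be dominated by those structural zeros. Inputs are
normalized per sample (z-score + min-max, see
:func:`celldeconv.preprocess.model_normalize`) outside the differentiated
graph; during training each normalized input is corrupted with additive
Gaussian noise and random zeroing to discourage reliance on any single
marker gene.

The forward/backward passes, Adam optimizer, plateau learning-rate schedule
and early stopping are implemented directly on NumPy arrays; the same
backward machinery exposes input gradients for integrated-gradients
attribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np

from .preprocess import corrupt, model_normalize
from .types import (
    AlignmentError,
    CellTypeCatalog,
    CheckpointError,
    ConfigError,
    DeconvolutionResult,
    MixtureBatch,
    TrainingError,
    canonical_gene_symbol,
)

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture + corruption settings. The full-scale configuration is
    28,867 genes, hidden (8192, 4096, 2048, 1024) and 840 outputs; the tiny
    preset used throughout the tests is (200; 256, 128, 64, 32; 8)."""

    n_genes: int
    hidden: tuple[int, ...] = (8192, 4096, 2048, 1024)
    n_outputs: int = 840
    activation: str = "elu"
    noise_sigma: float = 0.05
    input_dropout: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden = tuple(int(h) for h in self.hidden)
        if self.n_genes < 1 or self.n_outputs < 1 or any(h < 1 for h in self.hidden):
            raise ConfigError("all layer sizes must be >= 1")
        if len(self.hidden) < 2:
            raise ConfigError("need at least two hidden layers (embedding extraction)")
        if self.activation != "elu":
            raise ConfigError("only ELU activation is supported")


def parameter_count(cfg: ModelConfig) -> int:
    """Trainable parameters of the dense stack: sum of (fan_in + 1) * fan_out."""
    sizes = [cfg.n_genes, *cfg.hidden, cfg.n_outputs]
    return int(sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:])))


def _elu(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a, np.expm1(np.minimum(a, 0.0)))


def _elu_grad(a: np.ndarray, h: np.ndarray) -> np.ndarray:
    # f'(a) = 1 for a>0, else f(a)+1
    return np.where(a > 0, 1.0, h + 1.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DeconvModel:
    """Weights + metadata of a built (possibly trained) deconvolution network."""

    def __init__(
        self,
        cfg: ModelConfig,
        catalog: CellTypeCatalog,
        gene_symbols: list[str],
    ) -> None:
        if len(catalog) != cfg.n_outputs:
            raise ConfigError("catalog length must equal n_outputs")
        if len(gene_symbols) != cfg.n_genes:
            raise ConfigError("gene_symbols length must equal n_genes")
        self.cfg = cfg
        self.catalog = catalog
        self.gene_symbols = [canonical_gene_symbol(s) for s in gene_symbols]
        self._init_weights(np.random.default_rng(cfg.seed))

    def _init_weights(self, rng: np.random.Generator) -> None:
        sizes = [self.cfg.n_genes, *self.cfg.hidden, self.cfg.n_outputs]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.cfg)

    # ---- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray):
        """Returns (probs, caches); caches hold pre-activations and activations."""
        h = X
        pre, act = [], [X]
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = h @ W + b
            h = _elu(a)
            pre.append(a)
            act.append(h)
        z = h @ self.W[-1] + self.b[-1]
        p = _softmax(z)
        return p, (pre, act, z)

    def predict_proba(self, X_normalized: np.ndarray) -> np.ndarray:
        """Inference-mode forward on already model-normalized input."""
        X = np.atleast_2d(np.asarray(X_normalized, dtype=float))
        p, _ = self._forward(X)
        return p

    def hidden_activations(self, X_normalized: np.ndarray) -> list[np.ndarray]:
        """Post-activation values of every hidden layer (inference mode)."""
        X = np.atleast_2d(np.asarray(X_normalized, dtype=float))
        _, (pre, act, _) = self._forward(X)
        return act[1:]

    def _backward(self, dP: np.ndarray, caches) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradient of a scalar loss wrt all weights, given dLoss/dProbs."""
        pre, act, z = caches
        p = _softmax(z)
        # softmax Jacobian applied rowwise
        dz = p * (dP - (dP * p).sum(axis=1, keepdims=True))
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        g = dz
        for li in range(len(self.W) - 1, -1, -1):
            h_in = act[li]
            grads.append((h_in.T @ g, g.sum(axis=0)))
            if li > 0:
                g = (g @ self.W[li].T) * _elu_grad(pre[li - 1], act[li])
        grads.reverse()
        return grads

    def input_gradient(self, X_normalized: np.ndarray, target: int) -> np.ndarray:
        """d p_target / d x for each row of ``X_normalized`` (inference mode)."""
        X = np.atleast_2d(np.asarray(X_normalized, dtype=float))
        p, (pre, act, z) = self._forward(X)
        onehot = np.zeros_like(p)
        onehot[:, target] = 1.0
        dz = p[:, [target]] * (onehot - p)  # d p_t / d z
        g = dz @ self.W[-1].T
        for li in range(len(self.W) - 2, -1, -1):
            g = g * _elu_grad(pre[li], act[li + 1])
            g = g @ self.W[li].T
        return g


def build_model(
    cfg: ModelConfig,
    catalog: CellTypeCatalog,
    gene_symbols: list[str] | None = None,
) -> DeconvModel:
    """Build an untrained network for a catalog and gene vocabulary."""
    if gene_symbols is None:
        gene_symbols = [f"GENE{i}" for i in range(cfg.n_genes)]
    return DeconvModel(cfg, catalog, gene_symbols)


def sparse_mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Masked MSE: per-sample mean of squared errors over entries with
    y_true > 0 only, then mean over samples."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ConfigError("shape mismatch in sparse_mse")
    mask = y_true > 0
    n = mask.sum(axis=1)
    if np.any(n == 0):
        raise TrainingError("a sample has all-zero truth; not a valid mixture")
    per_sample = ((y_pred - y_true) ** 2 * mask).sum(axis=1) / n
    return float(per_sample.mean())


def _sparse_mse_grad(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    mask = y_true > 0
    n = mask.sum(axis=1, keepdims=True)
    return 2.0 * mask * (y_pred - y_true) / (n * y_true.shape[0])


@dataclass
class TrainParams:
    """Optimizer and schedule settings (Adam; plateau LR halving; early stop
    on the training-loss trace, both judged per epoch)."""

    lr: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 50
    val_frac: float = 0.2
    eval_interval: int = 5
    early_stop_patience: int = 4
    early_stop_delta: float = 1.25e-5
    lr_drop_factor: float = 0.5
    lr_drop_patience: int = 5
    lr_drop_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_frac < 1:
            raise ConfigError("val_frac must be in (0, 1)")
        if not 0 < self.lr_drop_factor < 1:
            raise ConfigError("lr_drop_factor must be in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[tuple[int, float]] = field(default_factory=list)  # (epoch, loss)
    lr_trace: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"
    stopped_epoch: int = 0


class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-7):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: DeconvModel,
    batch: MixtureBatch,
    p: TrainParams | None = None,
) -> tuple[DeconvModel, TrainHistory]:
    """Train on a mixture batch.

    Each input row is model-normalized once up front (the normalization is
    deterministic per row); every optimizer step corrupts its minibatch with
    fresh noise/dropout draws. The LR halves when the epoch training loss
    fails to improve by ``lr_drop_delta`` within ``lr_drop_patience`` epochs;
    training stops early when it fails to improve by ``early_stop_delta``
    within ``early_stop_patience`` epochs.
    """
    p = p or TrainParams()
    if batch.n_mixtures < p.batch_size:
        raise ConfigError("need at least batch_size mixtures")
    if batch.X.shape[1] != model.cfg.n_genes:
        raise ConfigError("gene width mismatch between batch and model")
    rng = np.random.default_rng(p.seed)
    corr_rng = np.random.default_rng(rng.integers(2**31))
    Xn = model_normalize(batch.X, already_log=True)
    Y = batch.Y
    n = Xn.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(p.val_frac * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    params = [*model.W, *model.b]
    opt = _Adam(params)
    lr = p.lr
    hist = TrainHistory()
    best_es = np.inf
    best_lr = np.inf
    es_wait = lr_wait = 0

    for epoch in range(1, p.max_epochs + 1):
        order = rng.permutation(tr_idx)
        losses = []
        for s in range(0, len(order) - p.batch_size + 1, p.batch_size):
            idx = order[s : s + p.batch_size]
            xb = corrupt(
                Xn[idx],
                noise_sigma=model.cfg.noise_sigma,
                dropout=model.cfg.input_dropout,
                rng=corr_rng,
            )
            yb = Y[idx]
            probs, caches = model._forward(xb)
            loss = sparse_mse(yb, probs)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            grads = model._backward(_sparse_mse_grad(yb, probs), caches)
            gw = [g[0] for g in grads] + [g[1] for g in grads]
            opt.step([*model.W, *model.b], gw, lr)
        epoch_loss = float(np.mean(losses))
        hist.train_loss.append(epoch_loss)
        hist.lr_trace.append(lr)
        hist.stopped_epoch = epoch

        if epoch % p.eval_interval == 0 or epoch == p.max_epochs:
            vp, _ = model._forward(Xn[val_idx])
            hist.val_loss.append((epoch, sparse_mse(Y[val_idx], vp)))

        if best_lr - epoch_loss > p.lr_drop_delta:
            best_lr = epoch_loss
            lr_wait = 0
        else:
            lr_wait += 1
            if lr_wait >= p.lr_drop_patience:
                lr *= p.lr_drop_factor
                lr_wait = 0
                log.info("epoch %d: plateau, lr -> %.3g", epoch, lr)

        if best_es - epoch_loss > p.early_stop_delta:
            best_es = epoch_loss
            es_wait = 0
        else:
            es_wait += 1
            if es_wait >= p.early_stop_patience:
                hist.stop_reason = "early_stop"
                break
    return model, hist


def align_genes(
    model: DeconvModel, X: np.ndarray, gene_symbols: list[str] | None
) -> np.ndarray:
    """Map input columns onto the model vocabulary: case-insensitive symbol
    match, missing genes zero-filled, unknown genes dropped. Raises when
    fewer than 10% of the model's genes are covered."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if gene_symbols is None:
        if X.shape[1] != model.cfg.n_genes:
            raise AlignmentError(
                f"input width {X.shape[1]} != model width {model.cfg.n_genes} "
                "and no gene symbols given"
            )
        return X
    pos = {g: i for i, g in enumerate(model.gene_symbols)}
    out = np.zeros((X.shape[0], model.cfg.n_genes))
    hits = 0
    for j, s in enumerate(gene_symbols):
        i = pos.get(canonical_gene_symbol(s))
        if i is not None:
            out[:, i] = X[:, j]
            hits += 1
    if hits < 0.1 * model.cfg.n_genes:
        raise AlignmentError(
            f"only {hits}/{model.cfg.n_genes} model genes found in input"
        )
    if hits < len(gene_symbols):
        log.info("dropped %d input genes outside model vocabulary",
                 len(gene_symbols) - hits)
    return out


def predict_fractions(
    model: DeconvModel,
    X: np.ndarray,
    already_log: bool = True,
    gene_symbols: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> DeconvolutionResult:
    """Deconvolve samples (corruption disabled; sample order preserved)."""
    X = align_genes(model, X, gene_symbols)
    Xn = model_normalize(X, already_log=already_log)
    probs = model.predict_proba(Xn)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(probs.shape[0])]
    return DeconvolutionResult(fractions=probs, catalog=model.catalog,
                               sample_ids=sample_ids)


def extract_embeddings(
    model: DeconvModel,
    X: np.ndarray,
    layers: tuple[int, ...] | None = None,
    already_log: bool = True,
    gene_symbols: list[str] | None = None,
) -> list[np.ndarray]:
    """Post-activation values of designated hidden layers per sample.

    Default layers are the middle two of the hidden stack — indices 1 and 2
    of a 4-layer stack (widths 4096 and 2048 at full scale).
    """
    L = len(model.cfg.hidden)
    if layers is None:
        layers = (L // 2 - 1, L // 2)
    for li in layers:
        if not 0 <= li < L:
            raise ConfigError(f"hidden layer index {li} out of range (0..{L-1})")
    X = align_genes(model, X, gene_symbols)
    Xn = model_normalize(X, already_log=already_log)
    act = model.hidden_activations(Xn)
    return [act[li] for li in layers]


# ---- checkpointing ---------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(model: DeconvModel, path) -> None:
    """Persist a model as a directory {weights.h5, config.json}."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "weights.h5", "w") as f:
        for i, (W, b) in enumerate(zip(model.W, model.b)):
            f.create_dataset(f"W{i}", data=W)
            f.create_dataset(f"b{i}", data=b)
    config = {
        "schema": CHECKPOINT_SCHEMA,
        "model": asdict(model.cfg),
        "catalog": model.catalog.type_names,
        "gene_symbols": model.gene_symbols,
        "normalization": {"per_input": "cpm10k-log2-zscore-minmax"},
    }
    (path / "config.json").write_text(json.dumps(config, indent=1))


def load_checkpoint(path) -> DeconvModel:
    """Load a checkpoint; predictions reproduce the saved model's exactly."""
    path = Path(path)
    try:
        config = json.loads((path / "config.json").read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise CheckpointError(f"cannot read config.json: {e}") from e
    if config.get("schema") != CHECKPOINT_SCHEMA:
        raise CheckpointError(f"unsupported checkpoint schema {config.get('schema')!r}")
    mc = config["model"]
    mc["hidden"] = tuple(mc["hidden"])
    cfg = ModelConfig(**mc)
    model = DeconvModel(cfg, CellTypeCatalog(config["catalog"]), config["gene_symbols"])
    try:
        with h5py.File(path / "weights.h5", "r") as f:
            for i in range(len(model.W)):
                W = np.asarray(f[f"W{i}"])
                b = np.asarray(f[f"b{i}"])
                if W.shape != model.W[i].shape or b.shape != model.b[i].shape:
                    raise CheckpointError(
                        f"layer {i}: weight shape {W.shape} does not match config"
                    )
                model.W[i] = W
                model.b[i] = b
    except (OSError, KeyError) as e:
        raise CheckpointError(f"cannot read weights.h5: {e}") from e
    return model
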