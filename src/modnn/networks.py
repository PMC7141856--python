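"""Encoder/combiner networks, weight accounting and training protocols.

The architecture is a *late-integration* (modular) multi-label classifier:

* one **encoder** per feature source — a fully connected net with hidden
  layers of 64, 32 and 16 rectified units (dropout 0.5 on hidden layers
  during training) and a per-class sigmoid output head;
* after an encoder is trained its output head is discarded and the 16 (by
  default) activations of its last hidden layer serve as a learned embedding
  of the gene;
* a **combiner** — hidden layers of 32 and 16 rectified units, no dropout —
  maps the concatenated encoder embeddings to the final per-class sigmoid
  probabilities.  Encoders stay frozen while the combiner trains.

Training is minibatch stochastic gradient descent on the mean per-class
binary cross-entropy, with early stopping on a held-out validation split.
Everything is deterministic under the configured seed.

The parameter count of a fully connected net with layer widths
``[n0, n1, ..., nL]`` is ``sum (n_{i}+1) * n_{i+1}`` (one bias per unit); the
default single-source encoder therefore has ``(n_feats+1)*64 + 3067``
trainable weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse

from .core_data import Dataset
from .seeding import derive_seed

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainedNetwork",
    "ModularModel",
    "FSSConfig",
    "count_trainable_weights",
    "encoder_spec",
    "combiner_spec",
    "train_network",
    "embed",
    "train_modular",
    "predict",
    "fss_select",
    "DEFAULT_EMBED_DIM",
    "PAPER_ARITHMETIC_EMBED_DIM",
]

#: Embedding width used throughout the text of the reference architecture.
DEFAULT_EMBED_DIM = 16
#: Alternative width under which the combiner weight arithmetic
#: (257*32 + 33*16 + 17*27 = 9211) is self-consistent: a 256-wide combiner
#: input, i.e. 64-dimensional per-module projections.
PAPER_ARITHMETIC_EMBED_DIM = 64


@dataclass(frozen=True)
class NetworkSpec:
    """Layer widths and regularisation of one fully connected net."""

    layer_sizes: tuple[int, ...]
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("a network needs at least input and output layers")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("all layer sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def embed_dim(self) -> int:
        """Width of the penultimate layer (the embedding the net exposes)."""
        return self.layer_sizes[-2]


def encoder_spec(n_feats: int, n_classes: int, d_embed: int = DEFAULT_EMBED_DIM,
                 dropout: float = 0.5) -> NetworkSpec:
    """Default per-source encoder: 64-32-d_embed hidden, dropout 0.5."""
    return NetworkSpec((n_feats, 64, 32, d_embed, n_classes), dropout=dropout)


def combiner_spec(n_blocks: int, n_classes: int,
                  d_embed: int = DEFAULT_EMBED_DIM) -> NetworkSpec:
    """Default combiner: 32-16 hidden over the concatenated embeddings."""
    return NetworkSpec((d_embed * n_blocks, 32, 16, n_classes), dropout=0.0)


def count_trainable_weights(
    spec: NetworkSpec | Sequence[int], include_output_layer: bool = True
) -> int:
    """Number of trainable weights (incl. biases) of a fully connected net.

    ``sum (a+1)*b`` over consecutive layer pairs; with
    ``include_output_layer=False`` the final pair is omitted (the encoder
    'body' left after removing the classification head).
    """
    sizes = spec.layer_sizes if isinstance(spec, NetworkSpec) else tuple(spec)
    if len(sizes) < 2:
        raise ValueError("need at least two layers")
    pairs = list(zip(sizes[:-1], sizes[1:]))
    if not include_output_layer:
        pairs = pairs[:-1]
    return int(sum((a + 1) * b for a, b in pairs))


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters; the seed fully determines init and batch order."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 200
    early_stopping_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.early_stopping_patience < 0:
            raise ValueError("patience must be >= 0")


def _as_dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=np.float64)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class TrainedNetwork:
    """A trained fully connected net: spec, per-layer weights, training log."""

    spec: NetworkSpec
    weights: list[np.ndarray]  # W[l]: (n_l, n_{l+1})
    biases: list[np.ndarray]  # b[l]: (n_{l+1},)
    training_log: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return int(
            sum(w.size for w in self.weights) + sum(b.size for b in self.biases)
        )

    def _forward_hidden(self, X) -> np.ndarray:
        h = _as_dense(X)
        if h.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"input width {h.shape[1]} != network input {self.spec.n_inputs}"
            )
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = _relu(h @ W + b)
        return h

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probabilities; dropout off (inference mode)."""
        h = self._forward_hidden(X)
        return _sigmoid(h @ self.weights[-1] + self.biases[-1])

    def embed(self, X) -> np.ndarray:
        """Last-hidden-layer activations (the embedding), dropout off."""
        return self._forward_hidden(X)

    @property
    def output_weights(self) -> np.ndarray:
        """Last-hidden -> output weight matrix, shape (embed_dim, n_outputs)."""
        return self.weights[-1]

    def copy(self) -> "TrainedNetwork":
        return TrainedNetwork(
            self.spec,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            list(self.training_log),
        )


def _init_params(
    spec: NetworkSpec, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for a, b in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:]):
        # He init for the rectified layers, Xavier-ish scale for the head
        scale = np.sqrt(2.0 / a)
        weights.append(rng.normal(0.0, scale, size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


def train_network(spec: NetworkSpec, X, Y, cfg: TrainConfig) -> TrainedNetwork:
    """Train a multi-label net by minibatch SGD on mean binary cross-entropy.

    A ``validation_fraction`` split (seed-determined) is held out for early
    stopping; the best-validation weights are restored.  Deterministic under
    ``cfg.seed``.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if X.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if X.shape[1] != spec.n_inputs or Y.shape[1] != spec.n_outputs:
        raise ValueError("data shape does not match network spec")

    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(spec, rng)
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    n_val = int(round(cfg.validation_fraction * n)) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[tr_idx], Y[tr_idx]
    X_val, Y_val = (X[val_idx], Y[val_idx]) if n_val else (None, None)

    n_tr = len(tr_idx)
    n_hidden = len(spec.layer_sizes) - 2
    best_val = np.inf
    best = None
    patience_left = cfg.early_stopping_patience
    log: list[tuple[int, float, float]] = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb = _as_dense(X_tr[batch])
            yb = Y_tr[batch]
            # forward with inverted dropout on hidden activations
            acts = [xb]
            masks = []
            h = xb
            for l in range(n_hidden):
                h = _relu(h @ weights[l] + biases[l])
                if spec.dropout > 0:
                    mask = (rng.random(h.shape) >= spec.dropout) / (1 - spec.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            p = _sigmoid(h @ weights[-1] + biases[-1])
            epoch_loss += _bce(p, yb) * len(batch)

            # backward: d(mean BCE)/dz_out = (p - y) / (B*C)
            delta = (p - yb) / (yb.shape[0] * yb.shape[1])
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            grads_w[-1] = acts[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            for l in range(n_hidden - 1, -1, -1):
                delta = delta @ weights[l + 1].T
                if masks[l] is not None:
                    delta = delta * masks[l]
                delta = delta * (acts[l + 1] > 0)
                grads_w[l] = acts[l].T @ delta
                grads_b[l] = delta.sum(axis=0)

            for l in range(len(weights)):
                vel_w[l] = cfg.momentum * vel_w[l] - cfg.learning_rate * grads_w[l]
                vel_b[l] = cfg.momentum * vel_b[l] - cfg.learning_rate * grads_b[l]
                weights[l] += vel_w[l]
                biases[l] += vel_b[l]

        train_loss = epoch_loss / max(n_tr, 1)
        net = TrainedNetwork(spec, weights, biases)
        if n_val:
            val_loss = _bce(net.predict_proba(X_val), Y_val)
        else:
            val_loss = train_loss
        log.append((epoch, train_loss, val_loss))

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = ([w.copy() for w in weights], [b.copy() for b in biases])
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if n_val and patience_left < 0:
                break

    if best is not None:
        weights, biases = best
    return TrainedNetwork(spec, weights, biases, log)


def embed(net: TrainedNetwork, X) -> np.ndarray:
    """Embedding (last hidden layer) of each row of X, inference mode."""
    return net.embed(X)


@dataclass
class ModularModel:
    """Per-block encoders + a combiner over their concatenated embeddings.

    Encoders are frozen once trained; every gene in the universe receives a
    prediction (genes unknown to a block contribute that encoder's response
    to the zero vector).
    """

    encoders: dict[str, TrainedNetwork]
    combiner: TrainedNetwork
    block_order: list[str]
    class_names: list[str]
    d_embed: int

    @property
    def output_weights(self) -> np.ndarray:
        """Combiner last-hidden -> output weights, shape (d, C); column c is
        the per-class projection vector used for embedding-space mining."""
        return self.combiner.output_weights

    def encoder_embeddings(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        """Concatenated per-block embeddings (combiner input) for ``genes``."""
        parts = []
        for bname in self.block_order:
            block = dataset.blocks[bname]
            X = block.dense_rows(genes, fill=0.0)
            parts.append(self.encoders[bname].embed(X))
        return np.hstack(parts)

    def combiner_embedding(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        """Combiner last-hidden-layer embedding of each gene."""
        return self.combiner.embed(self.encoder_embeddings(dataset, genes))

    def predict_proba(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        return self.combiner.predict_proba(self.encoder_embeddings(dataset, genes))


def train_encoders(
    dataset: Dataset,
    train_genes: Sequence[str],
    cfg: TrainConfig,
    d_embed: int = DEFAULT_EMBED_DIM,
    block_names: Sequence[str] | None = None,
) -> dict[str, TrainedNetwork]:
    """Train one encoder per block on the block's known training genes."""
    names = sorted(block_names if block_names is not None else dataset.blocks)
    encoders: dict[str, TrainedNetwork] = {}
    for bname in names:
        block = dataset.blocks[bname]
        known_train = [g for g in train_genes if g in block.known_genes]
        if not known_train:
            raise ValueError(f"block {bname!r} has no known training genes")
        X = block.dense_rows(known_train)
        Y = dataset.labels.rows(known_train)
        spec = encoder_spec(block.n_features, dataset.labels.n_classes, d_embed)
        enc_cfg = replace(cfg, seed=derive_seed(cfg.seed, "encoder", bname))
        encoders[bname] = train_network(spec, X, Y, enc_cfg)
    return encoders


def train_combiner(
    dataset: Dataset,
    encoders: dict[str, TrainedNetwork],
    train_genes: Sequence[str],
    cfg: TrainConfig,
    block_names: Sequence[str] | None = None,
) -> ModularModel:
    """Train the combiner over frozen encoders; returns the full model."""
    order = sorted(block_names if block_names is not None else encoders)
    d_embed = encoders[order[0]].spec.embed_dim
    parts = []
    for bname in order:
        block = dataset.blocks[bname]
        parts.append(encoders[bname].embed(block.dense_rows(train_genes)))
    Z = np.hstack(parts)
    Y = dataset.labels.rows(train_genes)
    spec = combiner_spec(len(order), dataset.labels.n_classes, d_embed)
    comb_cfg = replace(cfg, seed=derive_seed(cfg.seed, "combiner"))
    combiner = train_network(spec, Z, Y, comb_cfg)
    return ModularModel(
        {b: encoders[b] for b in order},
        combiner,
        order,
        list(dataset.labels.class_names),
        d_embed,
    )


def train_modular(
    dataset: Dataset,
    train_genes: Sequence[str],
    cfg: TrainConfig,
    d_embed: int = DEFAULT_EMBED_DIM,
    block_names: Sequence[str] | None = None,
) -> ModularModel:
    """Full modular protocol: encoders on their known training genes, then a
    combiner over the frozen encoders' embeddings of all training genes."""
    encoders = train_encoders(dataset, train_genes, cfg, d_embed, block_names)
    return train_combiner(dataset, encoders, train_genes, cfg, block_names)


def predict(model, dataset: Dataset, genes: Sequence[str],
            block_name: str | None = None) -> np.ndarray:
    """Per-gene per-class probabilities from a modular or single-block model.

    Single-block models (``TrainedNetwork``) need ``block_name`` so the
    genes' feature rows can be fetched (unknown genes are zero-filled; how
    their scores enter evaluation is the evaluation strategy's business).
    """
    if isinstance(model, ModularModel):
        return model.predict_proba(dataset, genes)
    if block_name is None:
        raise ValueError("block_name is required for single-block models")
    X = dataset.blocks[block_name].dense_rows(genes)
    return model.predict_proba(X)


@dataclass(frozen=True)
class FSSConfig:
    """Forward sequential selection of feature-source modules."""

    learn_fraction: float = 2.0 / 3.0
    improvement_epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learn_fraction < 1:
            raise ValueError("learn_fraction must be in (0,1)")
        if self.improvement_epsilon < 0:
            raise ValueError("improvement_epsilon must be >= 0")

    @property
    def eval_fraction(self) -> float:
        return 1.0 - self.learn_fraction


def fss_select(
    dataset: Dataset,
    train_genes: Sequence[str],
    cfg: TrainConfig,
    fss_cfg: FSSConfig,
    d_embed: int = DEFAULT_EMBED_DIM,
) -> tuple[list[str], ModularModel]:
    """Greedy forward selection of encoder modules.

    The training genes are split into a learning set (2/3) and an evaluation
    set (1/3).  Encoders are trained once on the learning set; candidate
    module sets are scored by retraining the combiner on the learning set and
    measuring macro-AUROC on the evaluation set.  The best single module is
    always kept; further modules are added while the score improves by more
    than ``improvement_epsilon``.  The returned model is retrained on all
    training genes using the selected blocks.
    """
    from .evaluation import macro_auroc  # local import avoids a cycle

    genes = sorted(train_genes)
    rng = np.random.default_rng(derive_seed(fss_cfg.seed, "fss-split"))
    perm = rng.permutation(len(genes))
    n_learn = int(round(fss_cfg.learn_fraction * len(genes)))
    learn = [genes[i] for i in sorted(perm[:n_learn])]
    ev = [genes[i] for i in sorted(perm[n_learn:])]
    Y_eval = dataset.labels.rows(ev)

    encoders = train_encoders(dataset, learn, cfg, d_embed)

    def score(block_set: list[str]) -> float:
        model = train_combiner(dataset, encoders, learn, cfg, block_set)
        return macro_auroc(model.predict_proba(dataset, ev), Y_eval)

    selected: list[str] = []
    best_score = -np.inf
    remaining = sorted(encoders)
    while remaining:
        cand_scores = {b: score(selected + [b]) for b in remaining}
        best_block = max(cand_scores, key=lambda b: (cand_scores[b], b))
        improved = cand_scores[best_block] > best_score + fss_cfg.improvement_epsilon
        if not selected or improved:
            selected.append(best_block)
            best_score = cand_scores[best_block]
            remaining.remove(best_block)
        else:
            break

    final = train_modular(dataset, genes, cfg, d_embed, block_names=selected)
    return selected, final
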