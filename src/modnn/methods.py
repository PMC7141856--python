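"""Registry of evaluable methods.

Every method is exposed as a *trainer*: a callable
``trainer(dataset, train_genes, seed) -> fitted`` where the fitted object
has ``predict_proba(dataset, genes)`` and a ``known_genes`` set (the genes
it can score from data; evaluation handles the rest per its unknown-gene
strategy).

Names:

* ``dnn:<block>``     — single-source network on one block
* ``dnn:concat``      — one network on all features concatenated
* ``modular``         — per-block encoders + combiner (late integration)
* ``fss``             — forward-selected modular network
* ``naive:<block>`` / ``naive:combined`` — annotation-popularity ranking
* ``bt:<block>`` / ``bt:concat``  — gradient-boosted trees per class
* ``lr:<block>`` / ``lr:concat``  — L2 logistic regression per class
* ``stacking:bt`` / ``stacking:lr`` — two-level stacking
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import baselines, networks
from .core_data import Dataset, concat_blocks
from .evaluation import Trainer

__all__ = ["build_trainer", "available_methods"]


@dataclass
class _FittedNetwork:
    net: networks.TrainedNetwork
    block_name: str
    known_genes: frozenset[str]
    _dataset_concat: object | None = None

    def predict_proba(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        if self._dataset_concat is not None:
            X = self._dataset_concat.dense_rows(genes)
        else:
            X = dataset.blocks[self.block_name].dense_rows(genes)
        return self.net.predict_proba(X)


@dataclass
class _FittedFlat:
    model: baselines.MultiLabelLearner
    block_name: str
    known_genes: frozenset[str]
    _dataset_concat: object | None = None

    def predict_proba(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        if self._dataset_concat is not None:
            X = self._dataset_concat.dense_rows(genes)
        else:
            X = dataset.blocks[self.block_name].dense_rows(genes)
        return self.model.predict_proba(X)


@dataclass
class _FittedNaive:
    scores: np.ndarray
    gene_index: dict[str, int]
    n_classes: int
    known_genes: frozenset[str]

    def predict_proba(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        s = np.array([self.scores[self.gene_index[g]] for g in genes])
        return np.tile(s[:, None], (1, self.n_classes))


def available_methods(dataset: Dataset) -> list[str]:
    blocks = sorted(dataset.blocks)
    names = [f"dnn:{b}" for b in blocks] + ["dnn:concat", "modular", "fss"]
    names += [f"naive:{b}" for b in blocks] + ["naive:combined"]
    for flat in ("bt", "lr"):
        names += [f"{flat}:{b}" for b in blocks] + [f"{flat}:concat", f"stacking:{flat}"]
    return names


def build_trainer(
    name: str,
    dataset: Dataset,
    train_cfg: networks.TrainConfig | None = None,
    fss_cfg: networks.FSSConfig | None = None,
    d_embed: int = networks.DEFAULT_EMBED_DIM,
) -> Trainer:
    """Trainer factory for a registry name; raises on unknown names."""
    from dataclasses import replace

    base_cfg = train_cfg or networks.TrainConfig()
    kind, _, arg = name.partition(":")
    universe_known = None  # lazily built concatenated block shared across folds

    def dnn_trainer(ds: Dataset, train_genes: Sequence[str], seed: int):
        cfg = replace(base_cfg, seed=seed)
        if arg == "concat":
            nonlocal universe_known
            if universe_known is None:
                universe_known = concat_blocks(ds)
            block = universe_known
            known = frozenset(ds.gene_universe)
        else:
            block = ds.blocks[arg]
            known = block.known_genes
        genes = [g for g in train_genes if g in known]
        X = block.dense_rows(genes)
        Y = ds.labels.rows(genes)
        spec = networks.encoder_spec(block.n_features, ds.labels.n_classes, d_embed)
        net = networks.train_network(spec, X, Y, cfg)
        return _FittedNetwork(net, arg, known,
                              universe_known if arg == "concat" else None)

    def modular_trainer(ds: Dataset, train_genes: Sequence[str], seed: int):
        cfg = replace(base_cfg, seed=seed)
        model = networks.train_modular(ds, list(train_genes), cfg, d_embed)
        model.known_genes = frozenset(ds.gene_universe)
        return model

    def fss_trainer(ds: Dataset, train_genes: Sequence[str], seed: int):
        cfg = replace(base_cfg, seed=seed)
        fss = fss_cfg or networks.FSSConfig()
        fss = replace(fss, seed=seed)
        _, model = networks.fss_select(ds, list(train_genes), cfg, fss, d_embed)
        model.known_genes = frozenset(ds.gene_universe)
        return model

    def naive_trainer(ds: Dataset, train_genes: Sequence[str], seed: int):
        scores = baselines.naive_scores(ds, arg)
        gi = {g: i for i, g in enumerate(scores.index)}
        return _FittedNaive(
            scores.to_numpy(), gi, ds.labels.n_classes, frozenset(ds.gene_universe)
        )

    def flat_trainer(ds: Dataset, train_genes: Sequence[str], seed: int):
        proto = (
            baselines.GradientBoostedTrees()
            if kind == "bt"
            else baselines.LogisticRegressionLearner()
        )
        if arg == "concat":
            nonlocal universe_known
            if universe_known is None:
                universe_known = concat_blocks(ds)
            block = universe_known
            known = frozenset(ds.gene_universe)
        else:
            block = ds.blocks[arg]
            known = block.known_genes
        genes = [g for g in train_genes if g in known]
        X = block.dense_rows(genes)
        Y = ds.labels.rows(genes)
        model = baselines.MultiLabelLearner(proto).fit(X, Y, seed)
        return _FittedFlat(model, arg, known,
                           universe_known if arg == "concat" else None)

    def stacking_trainer(ds: Dataset, train_genes: Sequence[str], seed: int):
        proto = (
            baselines.GradientBoostedTrees()
            if arg == "bt"
            else baselines.LogisticRegressionLearner()
        )
        return baselines.fit_stacking(ds, list(train_genes), proto, proto.clone(), seed)

    table = {
        "dnn": dnn_trainer,
        "modular": modular_trainer,
        "fss": fss_trainer,
        "naive": naive_trainer,
        "bt": flat_trainer,
        "lr": flat_trainer,
        "stacking": stacking_trainer,
    }
    if kind not in table or (kind in ("dnn", "naive", "bt", "lr") and not arg and kind != "dnn"):
        raise KeyError(
            f"unknown method {name!r}; available: {available_methods(dataset)}"
        )
    if kind in ("bt", "lr") and arg == "":
        raise KeyError(f"method {name!r} needs a block argument")
    if kind == "naive" and arg != "combined" and arg not in dataset.blocks:
        raise KeyError(f"naive source {arg!r} not in {sorted(dataset.blocks)}")
    if kind == "dnn" and arg != "concat" and arg not in dataset.blocks:
        raise KeyError(f"dnn block {arg!r} not in {sorted(dataset.blocks)}")
    return table[kind]
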