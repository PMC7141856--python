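"""Baseline classifiers: popularity ranking, flat learners, stacking.

The *naive popularity classifier* ranks genes by how intensely they have been
studied: for a sparse annotation source the score is the gene's annotation
count (0 if the gene is absent from the source); for the dense expression
source the score is 1 if the gene is present and 0 otherwise; the "combined"
source sums the per-source scores.  The same score vector serves every class
— the baseline exists to reveal how far a model's apparent skill reduces to
annotation-popularity bias.

Flat learners (gradient-boosted trees, L2 logistic regression) train one
independent binary model per class over a single block or the concatenated
features.  *Stacking* trains per-block base learners, turns their class
probabilities into meta-features (out-of-fold on the training split, to
avoid leakage) and fits a meta-learner on the n_blocks x C meta-feature
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .core_data import Dataset
from .seeding import derive_seed

__all__ = [
    "naive_scores",
    "BaseLearner",
    "GradientBoostedTrees",
    "LogisticRegressionLearner",
    "MultiLabelLearner",
    "StackedModel",
    "fit_stacking",
    "predict_stacking",
]


def naive_scores(dataset: Dataset, source: str) -> pd.Series:
    """Per-gene popularity score for one source or the 'combined' sum.

    The score is class-independent; its AUROC is invariant to any strictly
    monotone transform, so raw counts are used.
    """
    genes = list(dataset.gene_universe)
    if source == "combined":
        total = np.zeros(len(genes))
        for name in dataset.blocks:
            total += naive_scores(dataset, name).to_numpy()
        return pd.Series(total, index=genes, name="combined")
    if source not in dataset.blocks:
        raise KeyError(
            f"unknown source {source!r}; available: "
            f"{sorted(dataset.blocks)} or 'combined'"
        )
    block = dataset.blocks[source]
    scores = pd.Series(0.0, index=genes, name=source)
    if block.is_binary:
        counts = np.asarray(block.values.sum(axis=1)).ravel()
        scores.loc[block.gene_ids] = counts.astype(float)
    else:
        scores.loc[block.gene_ids] = 1.0
    return scores


class BaseLearner(Protocol):
    """A per-class binary learner: probabilities in [0,1], seed-deterministic."""

    name: str

    def fit(self, X, y: np.ndarray, seed: int) -> "BaseLearner": ...

    def predict_probabilities(self, X) -> np.ndarray: ...

    def clone(self) -> "BaseLearner": ...


@dataclass
class _ConstantLearner:
    """Fallback when a class has a single label value in training."""

    value: float

    def predict_probabilities(self, X) -> np.ndarray:
        return np.full(X.shape[0], self.value)


@dataclass
class GradientBoostedTrees:
    """Gradient-boosted tree learner (lightgbm backend)."""

    n_estimators: int = 100
    name: str = "bt"
    _model: object | None = field(default=None, repr=False)

    def clone(self) -> "GradientBoostedTrees":
        return GradientBoostedTrees(self.n_estimators, self.name)

    def fit(self, X, y: np.ndarray, seed: int) -> "GradientBoostedTrees":
        y = np.asarray(y).ravel()
        if len(np.unique(y)) < 2:
            self._model = _ConstantLearner(float(np.mean(y)))
            return self
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(
            n_estimators=self.n_estimators,
            random_state=seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
        model.fit(X, y)
        self._model = model
        return self

    def predict_probabilities(self, X) -> np.ndarray:
        if isinstance(self._model, _ConstantLearner):
            return self._model.predict_probabilities(X)
        return self._model.predict_proba(X)[:, 1]


@dataclass
class LogisticRegressionLearner:
    """L2-regularised logistic regression with library-default settings."""

    name: str = "lr"
    _model: object | None = field(default=None, repr=False)

    def clone(self) -> "LogisticRegressionLearner":
        return LogisticRegressionLearner(self.name)

    def fit(self, X, y: np.ndarray, seed: int) -> "LogisticRegressionLearner":
        y = np.asarray(y).ravel()
        if len(np.unique(y)) < 2:
            self._model = _ConstantLearner(float(np.mean(y)))
            return self
        # library defaults = L2 regularisation, C=1
        model = LogisticRegression(max_iter=1000, random_state=seed)
        model.fit(X, y)
        self._model = model
        return self

    def predict_probabilities(self, X) -> np.ndarray:
        if isinstance(self._model, _ConstantLearner):
            return self._model.predict_probabilities(X)
        return self._model.predict_proba(X)[:, 1]


@dataclass
class MultiLabelLearner:
    """One independent binary learner per class."""

    prototype: BaseLearner
    models: list[BaseLearner] = field(default_factory=list)

    def fit(self, X, Y: np.ndarray, seed: int) -> "MultiLabelLearner":
        Y = np.asarray(Y)
        self.models = [
            self.prototype.clone().fit(X, Y[:, c], derive_seed(seed, "class", c))
            for c in range(Y.shape[1])
        ]
        return self

    def predict_proba(self, X) -> np.ndarray:
        return np.column_stack([m.predict_probabilities(X) for m in self.models])


@dataclass
class StackedModel:
    """Per-block base learners + a meta-learner over their probabilities."""

    base_models: dict[str, MultiLabelLearner]
    meta_model: MultiLabelLearner
    block_order: list[str]
    class_names: list[str]
    fallback_freq: np.ndarray  # training-split class frequencies
    known_genes: frozenset[str] = frozenset()

    @property
    def meta_feature_layout(self) -> list[tuple[str, str]]:
        return [(b, c) for b in self.block_order for c in self.class_names]

    def meta_features(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        """Base-model class probabilities per block; genes unknown to a block
        get the training-split class frequencies for that block's columns."""
        parts = []
        for bname in self.block_order:
            block = dataset.blocks[bname]
            idx = block.row_index()
            out = np.tile(self.fallback_freq, (len(genes), 1))
            known_pos = [(j, g) for j, g in enumerate(genes) if g in idx]
            if known_pos:
                js = [j for j, _ in known_pos]
                X = block.dense_rows([g for _, g in known_pos])
                out[js] = self.base_models[bname].predict_proba(X)
            parts.append(out)
        return np.hstack(parts)

    def predict_proba(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray:
        return self.meta_model.predict_proba(self.meta_features(dataset, genes))


def fit_stacking(
    dataset: Dataset,
    train_genes: Sequence[str],
    base: BaseLearner,
    meta: BaseLearner,
    seed: int,
    n_inner_folds: int = 5,
) -> StackedModel:
    """Two-level stacking over the dataset's blocks.

    Meta-features for the training genes come from ``n_inner_folds``-fold
    out-of-fold prediction inside the training split, so the meta-learner
    never sees resubstitution probabilities.  Genes unknown to a block get
    the training-split class frequencies as that block's meta-features.
    """
    if len(dataset.blocks) < 2:
        raise ValueError("stacking needs at least two blocks")
    train_genes = list(train_genes)
    C = dataset.labels.n_classes
    Y_train = dataset.labels.rows(train_genes)
    fallback = Y_train.mean(axis=0)
    block_order = sorted(dataset.blocks)

    meta_parts = []
    base_models: dict[str, MultiLabelLearner] = {}
    for bname in block_order:
        block = dataset.blocks[bname]
        known_mask = np.array([g in block.known_genes for g in train_genes])
        known_genes_b = [g for g, m in zip(train_genes, known_mask) if m]
        oof = np.tile(fallback, (len(train_genes), 1))
        if known_genes_b:
            X = block.dense_rows(known_genes_b)
            Yb = dataset.labels.rows(known_genes_b)
            known_rows = np.flatnonzero(known_mask)
            n_splits = min(n_inner_folds, len(known_genes_b))
            if n_splits >= 2:
                kf = KFold(
                    n_splits=n_splits,
                    shuffle=True,
                    random_state=derive_seed(seed, "oof", bname),
                )
                for i, (tr, te) in enumerate(kf.split(X)):
                    fold_model = MultiLabelLearner(base).fit(
                        X[tr], Yb[tr], derive_seed(seed, "oof-fit", bname, i)
                    )
                    oof[known_rows[te]] = fold_model.predict_proba(X[te])
            # final base model on all known training genes (used at predict time)
            base_models[bname] = MultiLabelLearner(base).fit(
                X, Yb, derive_seed(seed, "base", bname)
            )
        meta_parts.append(oof)

    meta_X = np.hstack(meta_parts)
    meta_model = MultiLabelLearner(meta).fit(meta_X, Y_train, derive_seed(seed, "meta"))
    return StackedModel(
        base_models,
        meta_model,
        block_order,
        list(dataset.labels.class_names),
        fallback,
        known_genes=frozenset(dataset.gene_universe),
    )


def predict_stacking(
    model: StackedModel, dataset: Dataset, genes: Sequence[str]
) -> np.ndarray:
    """Gene x class probabilities from a fitted stacked model."""
    return model.predict_proba(dataset, genes)
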