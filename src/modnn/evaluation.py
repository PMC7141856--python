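"""Cross-validated macro-AUROC evaluation with unknown-gene strategies.

Performance is estimated by k-fold cross-validation over genes.  For each
fold, every class's AUROC is computed independently on the validation genes
and the per-fold macro average is the mean over classes with a defined AUROC
(a class with no positives or no negatives in the fold is skipped, not
imputed).  The overall score is the mean of the per-fold macros — this order
matters because the paired per-fold vectors feed the statistical comparison.

Genes *unknown* to a single-source model (no annotation of that source) are
handled by one of two strategies:

* ``all_genes``   — unknown validation genes are scored with the training
  split's class-label frequencies, so every gene is ranked;
* ``known_only``  — unknown validation genes are dropped before AUROC.

Scoring unknown genes by the (typically lower) class frequency tends to rank
them below true positives, which can inflate the all-genes AUROC; keeping
both strategies makes that visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import Dataset, FoldAssignment
from .seeding import derive_seed

__all__ = [
    "auroc",
    "macro_auroc",
    "CVResult",
    "evaluate_fold",
    "cross_validate",
    "Strategy",
]

Strategy = Literal["all_genes", "known_only"]


class FittedMethod(Protocol):
    """What evaluation needs from a fitted method."""

    known_genes: frozenset[str]

    def predict_proba(self, dataset: Dataset, genes: Sequence[str]) -> np.ndarray: ...


Trainer = Callable[[Dataset, Sequence[str], int], FittedMethod]


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic.

    Equals (wins + 0.5*ties) / (n_pos*n_neg) over all positive-negative
    pairs, with midranks for tied scores.  Returns NaN when the labels are
    single-class (undefined, not an error).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def macro_auroc(score_matrix: np.ndarray, label_matrix: np.ndarray) -> float:
    """Mean per-class AUROC over classes where it is defined."""
    per_class = [
        auroc(score_matrix[:, c], label_matrix[:, c])
        for c in range(label_matrix.shape[1])
    ]
    per_class = [a for a in per_class if not np.isnan(a)]
    return float(np.mean(per_class)) if per_class else float("nan")


@dataclass
class CVResult:
    """Fold x class AUROC grid with the macro-averaging rules applied."""

    method_name: str
    strategy: Strategy
    class_names: list[str]
    auroc_grid: np.ndarray  # (k, C), NaN where undefined

    @property
    def k(self) -> int:
        return self.auroc_grid.shape[0]

    @property
    def per_fold_macro(self) -> np.ndarray:
        """Macro average within each fold over classes with defined AUROC."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.auroc_grid, axis=1)

    @property
    def overall_macro(self) -> float:
        return float(np.mean(self.per_fold_macro))

    @property
    def per_class_mean(self) -> np.ndarray:
        """Per-disease AUROC averaged over the folds where it is defined."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.auroc_grid, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.auroc_grid,
            index=pd.RangeIndex(self.k, name="fold"),
            columns=self.class_names,
        )
        df["macro"] = self.per_fold_macro
        return df

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path.with_suffix(".tsv"), sep="\t")
        summary = {
            "method": self.method_name,
            "strategy": self.strategy,
            "overall_macro": self.overall_macro,
            "per_fold_macro": self.per_fold_macro.tolist(),
            "auroc_per_disease": dict(
                zip(self.class_names, np.round(self.per_class_mean, 6).tolist())
            ),
        }
        path.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def evaluate_fold(
    trainer: Trainer,
    dataset: Dataset,
    folds: FoldAssignment,
    fold_id: int,
    strategy: Strategy = "all_genes",
    seed: int | None = None,
) -> np.ndarray:
    """Per-class AUROC on one validation fold.

    The method is trained only on genes outside the fold.  Validation genes
    unknown to the method are frequency-filled (``all_genes``) or dropped
    (``known_only``).
    """
    if strategy not in ("all_genes", "known_only"):
        raise ValueError(f"unknown strategy {strategy!r}")
    train_genes = folds.genes_outside_fold(fold_id)
    val_genes = folds.genes_in_fold(fold_id)
    fit_seed = derive_seed(folds.seed if seed is None else seed, "fold", fold_id)
    model = trainer(dataset, train_genes, fit_seed)

    known = [g for g in val_genes if g in model.known_genes]
    unknown = [g for g in val_genes if g not in model.known_genes]

    if strategy == "known_only":
        eval_genes = known
        scores = model.predict_proba(dataset, known) if known else np.zeros((0, dataset.labels.n_classes))
    else:
        eval_genes = known + unknown
        train_freq = dataset.labels.rows(train_genes).mean(axis=0)
        parts = []
        if known:
            parts.append(model.predict_proba(dataset, known))
        if unknown:
            parts.append(np.tile(train_freq, (len(unknown), 1)))
        scores = np.vstack(parts) if parts else np.zeros((0, dataset.labels.n_classes))

    labels = dataset.labels.rows(eval_genes)
    return np.array(
        [auroc(scores[:, c], labels[:, c]) for c in range(dataset.labels.n_classes)]
    )


def cross_validate(
    trainer: Trainer,
    dataset: Dataset,
    folds: FoldAssignment,
    strategy: Strategy = "all_genes",
    method_name: str = "method",
    seed: int | None = None,
) -> CVResult:
    """Aggregate ``evaluate_fold`` over all folds into a CVResult."""
    grid = np.vstack(
        [
            evaluate_fold(trainer, dataset, folds, f, strategy, seed=seed)
            for f in range(folds.k)
        ]
    )
    return CVResult(method_name, strategy, list(dataset.labels.class_names), grid)
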