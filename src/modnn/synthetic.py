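"""Synthetic multi-source gene-disease benchmark generator.

Emulates the statistical structure of real multi-label gene-disease data so
the whole pipeline can be exercised end to end without any downloads:

* several sparse binary annotation blocks (GO-like, interaction-partner-like,
  pathway-like) plus an optional dense expression-like block;
* per-block *unknown* genes — genes absent from that source entirely;
* per-class label prevalence with optional pairwise co-occurrence;
* class-informative *signal features* whose activation rate is lifted for
  positively labelled genes;
* an annotation *popularity bias* coupling a gene's annotation count to its
  having any positive label (the confound a naive popularity ranker exploits);
* planted mislabelled negatives — genes whose true association is positive
  but whose recorded label is 0 — to measure candidate-mining recovery.

The generator makes no attempt to match real GO hierarchy, interaction
network topology or tissue covariance; it reproduces only the marginal and
pairwise structure listed above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import sparse

from .core_data import (
    Dataset,
    FeatureBlock,
    LabelMatrix,
    assemble_dataset,
    write_annotation_pairs,
    write_dense_matrix,
    write_labels,
)
from .seeding import derive_seed

__all__ = [
    "BlockSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "plant_negative_candidates",
    "write_synthetic",
    "DEFAULT_BLOCK_SPECS",
]


@dataclass(frozen=True)
class BlockSpec:
    """Shape of one synthetic feature source."""

    name: str
    n_features: int
    unknown_fraction: float = 0.0
    kind: Literal["binary", "dense"] = "binary"

    def __post_init__(self) -> None:
        if not 0.0 <= self.unknown_fraction < 1.0:
            raise ValueError(
                f"block {self.name!r}: unknown_fraction must be in [0,1), "
                f"got {self.unknown_fraction}"
            )
        if self.n_features < 1:
            raise ValueError(f"block {self.name!r}: n_features must be >= 1")


#: Default four-source layout mirroring the unknown-gene fractions of the
#: reference compilation (annotation sources at 4.0/19.4/16.8% unknown, the
#: expression source at 4.1%).
DEFAULT_BLOCK_SPECS: tuple[BlockSpec, ...] = (
    BlockSpec("go", 120, 0.040, "binary"),
    BlockSpec("ppi", 120, 0.194, "binary"),
    BlockSpec("pathway", 80, 0.168, "binary"),
    BlockSpec("expression", 40, 0.041, "dense"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``signal_strength`` is the probability lift added to a signal feature's
    base activation rate in genes positive for the feature's class (binary
    blocks) or the proportional mean shift (dense blocks).
    ``popularity_bias`` >= 0 multiplies the background annotation rate of any
    gene carrying at least one positive label by (1 + popularity_bias).
    ``label_correlation`` adds a shared latent Bernoulli factor to
    consecutive class pairs, boosting their co-occurrence.
    """

    n_genes: int = 2000
    block_specs: tuple[BlockSpec, ...] = DEFAULT_BLOCK_SPECS
    n_classes: int = 27
    prevalence: float | tuple[float, ...] = 0.1
    signal_features_per_class_per_block: int = 10
    signal_strength: float = 0.3
    popularity_bias: float = 0.0
    label_correlation: float = 0.0
    base_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        if not ((prev > 0) & (prev < 1)).all():
            raise ValueError("prevalence must be in (0,1)")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0,1]")
        if self.popularity_bias < 0:
            raise ValueError("popularity_bias must be >= 0")
        if not self.block_specs:
            raise ValueError("at least one block is required")
        for bs in self.block_specs:
            need = self.n_classes * self.signal_features_per_class_per_block
            if self.signal_features_per_class_per_block and bs.n_features < need:
                raise ValueError(
                    f"block {bs.name!r}: {bs.n_features} features cannot host "
                    f"{need} disjoint signal features "
                    f"({self.n_classes} classes x "
                    f"{self.signal_features_per_class_per_block})"
                )

    def prevalence_vector(self) -> np.ndarray:
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        if prev.size == 1:
            prev = np.repeat(prev, self.n_classes)
        if prev.size != self.n_classes:
            raise ValueError("prevalence length must match n_classes")
        return prev


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks.

    ``signal_feature_index[(class_name, block_name)]`` lists the informative
    feature indices; ``planted_candidates`` are (gene, class_name) pairs whose
    true association is positive but whose *recorded* label is 0.
    """

    signal_feature_index: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    planted_candidates: list[tuple[str, str]] = field(default_factory=list)


def _draw_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    prev = cfg.prevalence_vector()
    n, c = cfg.n_genes, cfg.n_classes
    labels = np.zeros((n, c), dtype=np.int8)
    if cfg.label_correlation > 0:
        # shared latent factor per consecutive class pair
        for a in range(0, c - 1, 2):
            b = a + 1
            q = min(cfg.label_correlation * min(prev[a], prev[b]), min(prev[a], prev[b]))
            latent = rng.random(n) < q
            for cls in (a, b):
                residual = (prev[cls] - q) / (1.0 - q) if q < 1 else 0.0
                labels[:, cls] = latent | (rng.random(n) < residual)
        if c % 2 == 1:
            labels[:, c - 1] = rng.random(n) < prev[c - 1]
    else:
        labels = (rng.random((n, c)) < prev[None, :]).astype(np.int8)
    return labels.astype(np.int8)


def _signal_indices(cfg: SyntheticConfig, bs: BlockSpec) -> dict[int, np.ndarray]:
    """Disjoint signal-feature indices per class: class c owns the c-th slice."""
    s = cfg.signal_features_per_class_per_block
    return {c: np.arange(c * s, (c + 1) * s) for c in range(cfg.n_classes)}


def _binary_block_values(
    cfg: SyntheticConfig,
    bs: BlockSpec,
    labels: np.ndarray,
    any_positive: np.ndarray,
    sig_idx: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> sparse.csr_matrix:
    n = cfg.n_genes
    rate = np.full((n, bs.n_features), cfg.base_rate)
    if cfg.popularity_bias > 0:
        rate[any_positive] *= 1.0 + cfg.popularity_bias
    for c, idx in sig_idx.items():
        pos = labels[:, c].astype(bool)
        if idx.size and pos.any():
            rate[np.ix_(pos, idx)] += cfg.signal_strength
    values = (rng.random((n, bs.n_features)) < np.clip(rate, 0, 1)).astype(np.int8)
    return sparse.csr_matrix(values)


def _dense_block_values(
    cfg: SyntheticConfig,
    bs: BlockSpec,
    labels: np.ndarray,
    sig_idx: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    # log-normal background resembles non-negative expression intensities
    n = cfg.n_genes
    values = rng.lognormal(mean=0.0, sigma=0.5, size=(n, bs.n_features))
    shift = 2.0 * cfg.signal_strength
    for c, idx in sig_idx.items():
        pos = labels[:, c].astype(bool)
        if idx.size and pos.any():
            values[np.ix_(pos, idx)] += shift
    return values


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset under ``cfg``; bit-identical under the same seed."""
    root = np.random.SeedSequence(cfg.seed)
    rng_labels = np.random.default_rng(derive_seed(cfg.seed, "labels"))
    labels_arr = _draw_labels(cfg, rng_labels)
    any_positive = labels_arr.any(axis=1)

    width = len(str(max(cfg.n_genes - 1, 1)))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]

    truth = GroundTruth()
    class_names = [f"disease{c:02d}" for c in range(cfg.n_classes)]
    labels = LabelMatrix(genes, class_names, labels_arr)

    # per-block unknown masks; repair genes unknown everywhere
    rng_unknown = np.random.default_rng(derive_seed(cfg.seed, "unknown"))
    unknown = {
        bs.name: rng_unknown.random(cfg.n_genes) < bs.unknown_fraction
        for bs in cfg.block_specs
    }
    known_count = np.sum([~m for m in unknown.values()], axis=0)
    orphan = np.flatnonzero(known_count == 0)
    if orphan.size:
        block_names = [bs.name for bs in cfg.block_specs]
        repair = rng_unknown.integers(0, len(block_names), size=orphan.size)
        for g, b in zip(orphan, repair):
            unknown[block_names[b]][g] = False

    blocks: dict[str, FeatureBlock] = {}
    for bs in cfg.block_specs:
        rng_block = np.random.default_rng(derive_seed(cfg.seed, "block", bs.name))
        sig_idx = _signal_indices(cfg, bs)
        for c, idx in sig_idx.items():
            truth.signal_feature_index[(class_names[c], bs.name)] = idx.tolist()
        if bs.kind == "binary":
            full = _binary_block_values(cfg, bs, labels_arr, any_positive, sig_idx, rng_block)
        else:
            full = _dense_block_values(cfg, bs, labels_arr, sig_idx, rng_block)
        keep = np.flatnonzero(~unknown[bs.name])
        block_genes = [genes[i] for i in keep]
        feat_ids = [f"{bs.name}_f{j}" for j in range(bs.n_features)]
        blocks[bs.name] = FeatureBlock(
            bs.name,
            block_genes,
            feat_ids,
            full[keep],
            is_binary=(bs.kind == "binary"),
        )

    dataset = assemble_dataset(blocks, labels)
    return dataset, truth


def plant_negative_candidates(
    dataset: Dataset,
    truth: GroundTruth,
    class_id: int | str,
    n: int,
    seed: int,
) -> tuple[Dataset, GroundTruth]:
    """Flip n recorded positives of one class to 0, leaving features untouched.

    The flipped genes model unreliable negative labels (absence of evidence
    rather than evidence of absence); they are recorded in
    ``GroundTruth.planted_candidates`` so mining recall can be measured.
    """
    labels = dataset.labels
    if isinstance(class_id, str):
        class_id = labels.class_names.index(class_id)
    class_name = labels.class_names[class_id]
    positives = np.flatnonzero(labels.values[:, class_id] == 1)
    if n > positives.size:
        raise ValueError(
            f"cannot plant {n} candidates: class {class_name!r} has only "
            f"{positives.size} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(positives, size=n, replace=False)
    new_values = labels.values.copy()
    new_values[chosen, class_id] = 0
    new_labels = LabelMatrix(list(labels.gene_ids), list(labels.class_names), new_values)
    new_truth = GroundTruth(
        signal_feature_index=dict(truth.signal_feature_index),
        planted_candidates=list(truth.planted_candidates)
        + [(labels.gene_ids[int(i)], class_name) for i in sorted(chosen)],
    )
    return Dataset(list(dataset.gene_universe), dict(dataset.blocks), new_labels), new_truth


def write_synthetic(dataset: Dataset, truth: GroundTruth, outdir: str | Path) -> None:
    """Write the dataset in the package's TSV formats plus a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, block in dataset.blocks.items():
        if block.is_binary:
            write_annotation_pairs(block, outdir / f"{name}.pairs.tsv")
        else:
            write_dense_matrix(block, outdir / f"{name}.matrix.tsv")
    write_labels(dataset.labels, outdir / "labels.tsv")
    sidecar = {
        "planted_candidates": [list(pc) for pc in truth.planted_candidates],
        "signal_feature_index": {
            f"{cls}|{blk}": idx for (cls, blk), idx in truth.signal_feature_index.items()
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
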