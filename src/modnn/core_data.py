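"""Data model and I/O for multi-source gene feature blocks, labels and folds.

A dataset bundles several *feature blocks* (one per biological data source:
GO-term annotations, protein-interaction partners, pathway memberships, tissue
expression, ...) over a common gene universe, together with a binary
gene x disease label matrix.  Annotation sources are sparse binary gene x term
matrices; expression sources are dense non-negative gene x tissue matrices.
A gene absent from a source (no annotation of that type at all) is *unknown*
to that block; downstream evaluation treats such genes specially.

File formats are deliberately plain:

* annotation pairs: two-column TSV ``gene_id<TAB>feature_id``, no header;
* dense matrices:   TSV with header ``gene_id<TAB>f1...fn``;
* labels:           TSV with header ``gene_id<TAB>class1...classC``, 0/1 cells;
* fold assignments: TSV ``gene_id<TAB>fold``.

Gene and feature orderings are canonicalized (sorted) after load so that all
downstream results are independent of file row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FeatureBlock",
    "LabelMatrix",
    "Dataset",
    "FoldAssignment",
    "read_annotation_pairs",
    "read_dense_matrix",
    "read_labels",
    "write_annotation_pairs",
    "write_dense_matrix",
    "write_labels",
    "assemble_dataset",
    "concat_blocks",
    "make_folds",
    "write_folds",
    "read_folds",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class FeatureBlock:
    """One feature source: a gene x feature matrix plus its known-gene set.

    ``values`` is a ``scipy.sparse.csr_matrix`` for binary annotation blocks
    and a dense ``numpy.ndarray`` for expression-like blocks.  Rows align with
    ``gene_ids``; only genes known to the source have a row.
    """

    name: str
    gene_ids: list[str]
    feature_ids: list[str]
    values: "sparse.csr_matrix | np.ndarray"
    is_binary: bool = True

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.gene_ids) or m != len(self.feature_ids):
            raise ValueError(
                f"block {self.name!r}: shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"block {self.name!r}: duplicate feature ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"block {self.name!r}: duplicate gene ids")
        if self.is_binary:
            data = self.values.data if sparse.issparse(self.values) else self.values
            if data.size and not np.isin(np.unique(data), [0, 1]).all():
                raise ValueError(f"block {self.name!r}: binary block has non-0/1 values")

    @property
    def known_genes(self) -> frozenset[str]:
        """Genes for which this source has any information."""
        return frozenset(self.gene_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def dense_rows(self, genes: Sequence[str], fill: float = 0.0) -> np.ndarray:
        """Dense feature rows for ``genes``; unknown genes get ``fill``."""
        idx = self.row_index()
        out = np.full((len(genes), self.n_features), fill, dtype=np.float64)
        rows = [(j, idx[g]) for j, g in enumerate(genes) if g in idx]
        if rows:
            js, src = map(list, zip(*rows))
            vals = self.values[src]
            out[js] = vals.toarray() if sparse.issparse(vals) else vals
        return out


@dataclass
class LabelMatrix:
    """Binary gene x disease annotation matrix (27 classes in the reference
    setting, configurable)."""

    gene_ids: list[str]
    class_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.class_names)):
            raise ValueError("label matrix shape mismatch")
        if self.values.size and not np.isin(np.unique(self.values), [0, 1]).all():
            raise ValueError("labels must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def class_frequencies(self) -> np.ndarray:
        """Per-class positive fraction (column means)."""
        if not self.gene_ids:
            return np.zeros(self.n_classes)
        return self.values.mean(axis=0)

    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def rows(self, genes: Sequence[str]) -> np.ndarray:
        idx = self.row_index()
        return self.values[[idx[g] for g in genes]]


@dataclass
class Dataset:
    """Gene universe + named feature blocks + labels.

    Invariant: every gene in the universe is known in at least one block, so
    the concatenated and modular settings cover 100% of the genes.
    """

    gene_universe: list[str]
    blocks: dict[str, FeatureBlock]
    labels: LabelMatrix

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    def unknown_genes(self, block_name: str) -> frozenset[str]:
        return frozenset(self.gene_universe) - self.blocks[block_name].known_genes

    def unknown_fraction(self, block_name: str) -> float:
        return len(self.unknown_genes(block_name)) / len(self.gene_universe)


@dataclass
class FoldAssignment:
    """A k-way partition of the gene universe (fold sizes differ by <= 1)."""

    k: int
    fold_of_gene: dict[str, int]
    seed: int

    def genes_in_fold(self, fold_id: int) -> list[str]:
        return sorted(g for g, f in self.fold_of_gene.items() if f == fold_id)

    def genes_outside_fold(self, fold_id: int) -> list[str]:
        return sorted(g for g, f in self.fold_of_gene.items() if f != fold_id)


# ---------------------------------------------------------------------------
# Readers / writers


def read_annotation_pairs(path: str | Path, block_name: str) -> FeatureBlock:
    """Read a sparse binary block from a two-column gene/term TSV.

    Duplicate pairs are idempotent (the cell stays 1).  Genes and features are
    sorted lexicographically after load.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            pairs.add((parts[0], parts[1]))
    genes = sorted({g for g, _ in pairs})
    feats = sorted({t for _, t in pairs})
    gi = {g: i for i, g in enumerate(genes)}
    fi = {t: i for i, t in enumerate(feats)}
    rows = [gi[g] for g, t in pairs]
    cols = [fi[t] for g, t in pairs]
    values = sparse.csr_matrix(
        (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
        shape=(len(genes), len(feats)),
    )
    return FeatureBlock(block_name, genes, feats, values, is_binary=True)


def write_annotation_pairs(block: FeatureBlock, path: str | Path) -> None:
    coo = sparse.coo_matrix(block.values)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(zip(coo.row.tolist(), coo.col.tolist())):
            fh.write(f"{block.gene_ids[i]}\t{block.feature_ids[j]}\n")


def read_dense_matrix(path: str | Path, block_name: str) -> FeatureBlock:
    """Read a dense block from a headered TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df["gene_id"].duplicated().any():
        dups = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups}")
    df = df.set_index("gene_id").sort_index()
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    if np.isnan(values).any():
        raise ParseError(f"{path}: missing cells are not allowed")
    return FeatureBlock(
        block_name, list(df.index), list(df.columns), values, is_binary=False
    )


def write_dense_matrix(block: FeatureBlock, path: str | Path) -> None:
    values = block.values.toarray() if sparse.issparse(block.values) else block.values
    df = pd.DataFrame(values, index=block.gene_ids, columns=block.feature_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_labels(path: str | Path) -> LabelMatrix:
    """Read the gene x class binary label matrix from a headered TSV."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id").sort_index()
    values = df.to_numpy()
    if values.size and not np.isin(np.unique(values), [0, 1]).all():
        raise ParseError(f"{path}: label cells must be 0 or 1")
    return LabelMatrix(list(df.index), list(df.columns), values.astype(np.int8))


def write_labels(labels: LabelMatrix, path: str | Path) -> None:
    df = pd.DataFrame(labels.values, index=labels.gene_ids, columns=labels.class_names)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_folds(folds: FoldAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(folds.fold_of_gene):
            fh.write(f"{g}\t{folds.fold_of_gene[g]}\n")


def read_folds(path: str | Path, k: int | None = None, seed: int = 0) -> FoldAssignment:
    fold_of_gene: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                g, f = line.rstrip("\n").split("\t")
                fold_of_gene[g] = int(f)
    if k is None:
        k = max(fold_of_gene.values()) + 1
    return FoldAssignment(k, fold_of_gene, seed)


# ---------------------------------------------------------------------------
# Assembly and derived structures


def assemble_dataset(
    blocks: Mapping[str, FeatureBlock] | Sequence[FeatureBlock],
    labels: LabelMatrix,
) -> Dataset:
    """Bundle blocks and labels; the gene universe is the label gene list.

    Raises if any gene is unknown in *every* block — such a gene carries no
    information in any setting and would break full-coverage guarantees.
    """
    if not isinstance(blocks, Mapping):
        blocks = {b.name: b for b in blocks}
    universe = list(labels.gene_ids)
    known_somewhere: set[str] = set()
    for b in blocks.values():
        known_somewhere |= b.known_genes
    orphans = [g for g in universe if g not in known_somewhere]
    if orphans:
        raise ValueError(
            f"{len(orphans)} gene(s) known in no block: {orphans[:10]}"
        )
    return Dataset(universe, dict(blocks), labels)


def concat_blocks(dataset: Dataset, name: str = "concat") -> FeatureBlock:
    """Concatenate all blocks over the full gene universe.

    Genes unknown to a block contribute zeros for that block's columns, so the
    concatenated setting has no unknown genes.  Feature count is the sum of
    block widths.
    """
    genes = list(dataset.gene_universe)
    parts = []
    feat_ids: list[str] = []
    all_binary = True
    for bname, block in dataset.blocks.items():
        parts.append(block.dense_rows(genes, fill=0.0))
        feat_ids.extend(f"{bname}:{f}" for f in block.feature_ids)
        all_binary = all_binary and block.is_binary
    values = np.hstack(parts) if parts else np.zeros((len(genes), 0))
    return FeatureBlock(name, genes, feat_ids, values, is_binary=all_binary)


def make_folds(dataset: Dataset, k: int, seed: int) -> FoldAssignment:
    """Uniform random k-way partition with fold sizes differing by at most 1.

    Plain random (not label-stratified): rare labels may be absent from some
    folds; evaluation marks the affected per-class scores undefined rather
    than imputing them.
    """
    genes = sorted(dataset.gene_universe)
    n = len(genes)
    if not 2 <= k <= n:
        raise ValueError(f"fold count k={k} must satisfy 2 <= k <= n_genes={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of_gene = {genes[int(g)]: int(i % k) for i, g in enumerate(order)}
    return FoldAssignment(k, fold_of_gene, seed)
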