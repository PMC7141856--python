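import numpy as np
import pytest
from scipy import sparse

from modnn.core_data import Dataset, FeatureBlock, LabelMatrix, assemble_dataset
from modnn.synthetic import BlockSpec, SyntheticConfig, generate_dataset


def make_block(name, genes, feats, rows, binary=True):
    values = np.asarray(rows, dtype=float)
    if binary:
        values = sparse.csr_matrix(values.astype(np.int8))
    return FeatureBlock(name, list(genes), list(feats), values, is_binary=binary)


@pytest.fixture
def tiny_dataset():
    """4 genes, 2 binary blocks + 1 dense block, 2 classes; gD unknown to A."""
    genes = ["gA", "gB", "gC", "gD"]
    block_a = make_block("alpha", ["gA", "gB", "gC"], ["t1", "t2", "t3"],
                         [[1, 1, 0], [1, 0, 0], [0, 1, 1]])
    block_b = make_block("beta", genes, ["u1", "u2"],
                         [[1, 0], [0, 0], [1, 1], [0, 1]])
    block_e = make_block("expr", ["gA", "gB", "gD"], ["tis1", "tis2"],
                         [[0.5, 1.2], [2.0, 0.1], [0.7, 0.7]], binary=False)
    labels = LabelMatrix(genes, ["d1", "d2"],
                         np.array([[1, 0], [0, 1], [1, 1], [0, 0]]))
    return assemble_dataset({"alpha": block_a, "beta": block_b, "expr": block_e},
                            labels)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 400-gene 3-class dataset with moderate signal, shared across tests."""
    cfg = SyntheticConfig(
        n_genes=400,
        n_classes=3,
        seed=11,
        prevalence=0.15,
        signal_strength=0.4,
        signal_features_per_class_per_block=8,
        block_specs=(
            BlockSpec("a", 40, 0.05),
            BlockSpec("b", 40, 0.15),
            BlockSpec("e", 30, 0.05, "dense"),
        ),
    )
    return generate_dataset(cfg)
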