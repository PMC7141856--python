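"""Weight accounting, training determinism, embeddings, modular protocol, FSS."""

import numpy as np
import pytest

from modnn.core_data import assemble_dataset
from modnn.networks import (
    DEFAULT_EMBED_DIM,
    PAPER_ARITHMETIC_EMBED_DIM,
    FSSConfig,
    NetworkSpec,
    TrainConfig,
    combiner_spec,
    count_trainable_weights,
    encoder_spec,
    fss_select,
    train_modular,
    train_network,
)
from modnn.synthetic import BlockSpec, SyntheticConfig, generate_dataset


class TestWeightAccounting:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([13615, 64, 32, 16, 27], 874_491),
            ([13887, 64, 32, 16, 27], 891_899),
            ([4790, 64, 32, 16, 27], 309_691),
            ([84, 64, 32, 16, 27], 8_507),
            ([32376, 64, 32, 16, 27], 2_075_195),
            ([256, 32, 16, 27], 9_211),
            ([1, 1], 2),
        ],
    )
    def test_reference_architecture_counts(self, sizes, expected):
        assert count_trainable_weights(sizes) == expected

    def test_encoder_closed_form(self):
        # (n_feats+1)*64 + 3067 for the default encoder with its head
        for n_feats in (84, 4790, 13615):
            spec = encoder_spec(n_feats, 27)
            assert count_trainable_weights(spec) == (n_feats + 1) * 64 + 3067

    def test_encoder_bodies_sum(self):
        body = lambda n: count_trainable_weights(
            [n, 64, 32, 16, 27], include_output_layer=False
        )
        total = sum(body(n) for n in (13615, 13887, 4790, 84))
        assert total == 2_082_752
        # plus the 256-input combiner head gives the full modular total
        assert total + count_trainable_weights([256, 32, 16, 27]) == 2_091_963

    def test_combiner_spec_widths(self):
        spec = combiner_spec(4, 27, d_embed=PAPER_ARITHMETIC_EMBED_DIM)
        assert spec.layer_sizes == (256, 32, 16, 27)
        spec16 = combiner_spec(4, 27, d_embed=DEFAULT_EMBED_DIM)
        assert spec16.layer_sizes == (64, 32, 16, 27)

    def test_count_matches_engine_introspection(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            depth = rng.integers(2, 6)
            sizes = tuple(int(s) for s in rng.integers(1, 40, size=depth))
            spec = NetworkSpec(sizes)
            X = rng.random((12, sizes[0]))
            Y = rng.integers(0, 2, size=(12, sizes[-1]))
            net = train_network(spec, X, Y, TrainConfig(max_epochs=1, seed=0))
            assert net.n_parameters == count_trainable_weights(spec)

    def test_monotone_in_layer_width(self):
        base = [50, 64, 32, 16, 27]
        ref = count_trainable_weights(base)
        for i in range(len(base)):
            wider = list(base)
            wider[i] += 1
            assert count_trainable_weights(wider) > ref

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError):
            count_trainable_weights([10])


class TestTraining:
    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 6))
        Y = rng.integers(0, 2, size=(40, 2))
        spec = NetworkSpec((6, 8, 4, 2), dropout=0.5)
        cfg = TrainConfig(max_epochs=5, seed=42)
        a = train_network(spec, X, Y, cfg)
        b = train_network(spec, X, Y, cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_outputs_are_probabilities(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 5))
        Y = rng.integers(0, 2, size=(30, 3))
        net = train_network(NetworkSpec((5, 8, 3)), X, Y,
                            TrainConfig(max_epochs=3, seed=0))
        P = net.predict_proba(X)
        assert P.shape == (30, 3)
        assert ((P >= 0) & (P <= 1)).all()

    def test_separable_toy_reaches_high_training_auroc(self):
        from modnn.evaluation import auroc

        rng = np.random.default_rng(7)
        n = 200
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([y + 0.1 * rng.standard_normal(n),
                             -y + 0.1 * rng.standard_normal(n)])
        net = train_network(NetworkSpec((2, 8, 4, 1)), X, y[:, None],
                            TrainConfig(max_epochs=100, seed=0))
        assert auroc(net.predict_proba(X)[:, 0], y) > 0.95

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_network(NetworkSpec((3, 2)), np.zeros((0, 3)),
                          np.zeros((0, 2)), TrainConfig())

    def test_training_log_populated(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 4))
        Y = rng.integers(0, 2, size=(50, 2))
        net = train_network(NetworkSpec((4, 6, 2)), X, Y,
                            TrainConfig(max_epochs=8, seed=0))
        assert len(net.training_log) >= 1
        epochs, train_losses, val_losses = zip(*net.training_log)
        assert all(np.isfinite(train_losses)) and all(np.isfinite(val_losses))


class TestEmbedding:
    def test_embedding_width_is_penultimate_layer(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 10))
        Y = rng.integers(0, 2, size=(30, 3))
        net = train_network(encoder_spec(10, 3), X, Y,
                            TrainConfig(max_epochs=2, seed=0))
        assert net.embed(X).shape == (30, DEFAULT_EMBED_DIM)

    def test_zero_rows_share_one_embedding(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 4))
        Y = rng.integers(0, 2, size=(30, 2))
        net = train_network(NetworkSpec((4, 6, 3, 2)), X, Y,
                            TrainConfig(max_epochs=2, seed=0))
        Z = net.embed(np.zeros((3, 4)))
        assert np.ptp(Z, axis=0).max() == 0.0

    def test_inference_is_deterministic_despite_dropout_spec(self):
        rng = np.random.default_rng(5)
        X = rng.random((20, 4))
        Y = rng.integers(0, 2, size=(20, 2))
        net = train_network(NetworkSpec((4, 6, 2), dropout=0.5), X, Y,
                            TrainConfig(max_epochs=2, seed=0))
        np.testing.assert_array_equal(net.embed(X), net.embed(X))

    def test_width_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.random((20, 4))
        Y = rng.integers(0, 2, size=(20, 2))
        net = train_network(NetworkSpec((4, 6, 2)), X, Y,
                            TrainConfig(max_epochs=1, seed=0))
        with pytest.raises(ValueError, match="width"):
            net.embed(np.zeros((2, 5)))


@pytest.fixture(scope="module")
def trained_modular(small_synthetic_module):
    ds, _ = small_synthetic_module
    cfg = TrainConfig(max_epochs=15, seed=0)
    genes = ds.gene_universe[: 300]
    return ds, genes, train_modular(ds, genes, cfg)


@pytest.fixture(scope="module")
def small_synthetic_module():
    cfg = SyntheticConfig(
        n_genes=400, n_classes=3, seed=11, prevalence=0.15,
        signal_strength=0.4, signal_features_per_class_per_block=8,
        block_specs=(BlockSpec("a", 40, 0.05), BlockSpec("b", 40, 0.15),
                     BlockSpec("e", 30, 0.05, "dense")),
    )
    return generate_dataset(cfg)


class TestModular:
    def test_combiner_input_width(self, trained_modular):
        ds, genes, model = trained_modular
        n_blocks = len(ds.blocks)
        assert model.combiner.spec.n_inputs == DEFAULT_EMBED_DIM * n_blocks
        Z = model.encoder_embeddings(ds, genes[:5])
        assert Z.shape == (5, DEFAULT_EMBED_DIM * n_blocks)

    def test_encoders_frozen_through_combiner_training(self, small_synthetic_module):
        from modnn.networks import train_combiner, train_encoders

        ds, _ = small_synthetic_module
        cfg = TrainConfig(max_epochs=5, seed=0)
        genes = ds.gene_universe[:200]
        encoders = train_encoders(ds, genes, cfg)
        before = {
            n: [w.copy() for w in e.weights] for n, e in encoders.items()
        }
        train_combiner(ds, encoders, genes, cfg)
        for n, e in encoders.items():
            for w_before, w_after in zip(before[n], e.weights):
                np.testing.assert_array_equal(w_before, w_after)

    def test_every_gene_predicted(self, trained_modular):
        ds, _, model = trained_modular
        P = model.predict_proba(ds, ds.gene_universe)
        assert P.shape == (len(ds.gene_universe), ds.labels.n_classes)
        assert ((P >= 0) & (P <= 1)).all()
        assert np.isfinite(P).all()

    def test_output_weights_shape(self, trained_modular):
        ds, _, model = trained_modular
        assert model.output_weights.shape == (16, ds.labels.n_classes)


class TestFSS:
    @staticmethod
    def _one_signal_dataset(seed=0):
        sig = SyntheticConfig(
            n_genes=800, n_classes=3, seed=seed, prevalence=0.12,
            signal_strength=0.5, signal_features_per_class_per_block=15,
            block_specs=(BlockSpec("b", 50, 0.05),),
        )
        noise = SyntheticConfig(
            n_genes=800, n_classes=3, seed=seed + 1, prevalence=0.12,
            signal_strength=0.0, signal_features_per_class_per_block=0,
            block_specs=(BlockSpec("a", 50, 0.05), BlockSpec("c", 50, 0.05)),
        )
        ds_sig, _ = generate_dataset(sig)
        ds_noise, _ = generate_dataset(noise)
        blocks = {"b": ds_sig.blocks["b"], "a": ds_noise.blocks["a"],
                  "c": ds_noise.blocks["c"]}
        return assemble_dataset(blocks, ds_sig.labels)

    def test_signal_block_selected_first_and_selection_stops(self):
        ds = self._one_signal_dataset()
        cfg = TrainConfig(max_epochs=40, seed=0)
        selected, model = fss_select(
            ds, ds.gene_universe, cfg, FSSConfig(seed=0, improvement_epsilon=0.005)
        )
        assert selected[0] == "b"
        assert set(selected) <= set(ds.blocks)
        assert len(selected) == len(set(selected))
        assert set(model.block_order) == set(selected)

    def test_pure_noise_keeps_single_module(self):
        noise = SyntheticConfig(
            n_genes=400, n_classes=2, seed=3, prevalence=0.15,
            signal_strength=0.0, signal_features_per_class_per_block=0,
            block_specs=(BlockSpec("a", 30, 0.0), BlockSpec("b", 30, 0.0)),
        )
        ds, _ = generate_dataset(noise)
        cfg = TrainConfig(max_epochs=10, seed=0)
        selected, _ = fss_select(
            ds, ds.gene_universe, cfg, FSSConfig(seed=0, improvement_epsilon=0.01)
        )
        assert len(selected) >= 1  # mandatory first pick
        assert set(selected) <= {"a", "b"}
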