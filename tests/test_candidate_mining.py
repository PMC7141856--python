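"""k-NN candidate mining, weighted projections and probability ranking."""

import numpy as np
import pytest

from modnn.candidate_mining import (
    MiningConfig,
    class_weighted_embeddings,
    knn_negative_candidates,
    probability_ranking,
)


def brute_force_candidates(projection, y, cfg):
    """Exhaustive pairwise-distance reimplementation of the k-NN filter."""
    n = len(projection)
    out = []
    for i in range(n):
        if y[i] != 0:
            continue
        d = [(np.sum((projection[j] - projection[i]) ** 2), j)
             for j in range(n) if j != i]
        d.sort()
        nn = [j for _, j in d[: cfg.knn_k]]
        if sum(int(y[j]) for j in nn) >= cfg.min_positive_neighbours:
            out.append(i)
    return out


class TestKnnCandidates:
    def test_negative_inside_positive_cluster_selected(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(0, 0.05, size=(10, 2))
        far = rng.normal(5, 0.05, size=(20, 2))
        proj = np.vstack([[0.0, 0.0], pos, far])
        y = np.array([0] + [1] * 10 + [0] * 20)
        hits = knn_negative_candidates(proj, y, 0, MiningConfig())
        selected = {i for i, _ in hits}
        assert 0 in selected
        idx, nn = next((i, nn) for i, nn in hits if i == 0)
        assert int(y[nn].sum()) == 10

    def test_eight_of_ten_positive_not_selected(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 0.05, size=(8, 2))
        near_neg = rng.normal(0, 0.05, size=(2, 2))
        far = rng.normal(5, 0.05, size=(15, 2))
        proj = np.vstack([[0.0, 0.0], pos, near_neg, far])
        y = np.array([0] + [1] * 8 + [0] * 2 + [0] * 15)
        hits = knn_negative_candidates(proj, y, 0, MiningConfig())
        assert 0 not in {i for i, _ in hits}

    def test_no_negatives_gives_empty_list(self):
        rng = np.random.default_rng(2)
        proj = rng.normal(size=(12, 3))
        y = np.ones(12, dtype=int)
        assert knn_negative_candidates(proj, y, 0, MiningConfig()) == []

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="knn_k"):
            knn_negative_candidates(np.zeros((5, 2)), np.zeros(5), 0,
                                    MiningConfig())

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        cfg = MiningConfig(knn_k=5, min_positive_neighbours=4)
        for trial in range(50):
            n = int(rng.integers(12, 60))
            proj = rng.normal(size=(n, 3))
            y = rng.integers(0, 2, size=n)
            hits = knn_negative_candidates(proj, y, 0, cfg)
            assert sorted(i for i, _ in hits) == brute_force_candidates(proj, y, cfg)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        proj = rng.normal(size=(80, 2))
        y = rng.integers(0, 2, size=80)
        sets = []
        for t in (5, 7, 9):
            cfg = MiningConfig(knn_k=10, min_positive_neighbours=t)
            sets.append({i for i, _ in knn_negative_candidates(proj, y, 0, cfg)})
        assert sets[2] <= sets[1] <= sets[0]

    def test_distance_ties_break_by_identifier(self):
        # four equidistant neighbours, knn_k=2: lexicographically first ids win
        proj = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0],
                         [0.0, 1.0], [0.0, -1.0]])
        ids = ["q", "c", "a", "d", "b"]
        y = np.array([0, 1, 1, 1, 1])
        cfg = MiningConfig(knn_k=2, min_positive_neighbours=2)
        hits = knn_negative_candidates(proj, y, 0, cfg, gene_ids=ids)
        (_, nn), = hits
        assert sorted(ids[j] for j in nn) == ["a", "b"]


class TestWeightedEmbeddings:
    def test_projection_scales_by_output_weight_column(self, small_synthetic):
        from modnn.networks import TrainConfig, train_modular

        ds, _ = small_synthetic
        model = train_modular(ds, ds.gene_universe[:200],
                              TrainConfig(max_epochs=5, seed=0))
        genes = ds.gene_universe[:20]
        emb = model.combiner_embedding(ds, genes)
        for c in range(ds.labels.n_classes):
            proj = class_weighted_embeddings(model, ds, c, genes)
            np.testing.assert_allclose(
                proj, emb * model.output_weights[:, c][None, :]
            )
        assert proj.shape == (20, 16)

    def test_identical_embeddings_identical_projections(self, small_synthetic):
        from modnn.networks import TrainConfig, train_modular

        ds, _ = small_synthetic
        model = train_modular(ds, ds.gene_universe[:200],
                              TrainConfig(max_epochs=5, seed=0))
        g = ds.gene_universe[0]
        p1 = class_weighted_embeddings(model, ds, 0, [g, g])
        np.testing.assert_array_equal(p1[0], p1[1])

    def test_invalid_class_rejected(self, small_synthetic):
        from modnn.networks import TrainConfig, train_modular

        ds, _ = small_synthetic
        model = train_modular(ds, ds.gene_universe[:200],
                              TrainConfig(max_epochs=2, seed=0))
        with pytest.raises(IndexError):
            class_weighted_embeddings(model, ds, ds.labels.n_classes)


class TestProbabilityRanking:
    def test_avg_min_max_across_runs(self):
        probs = np.zeros((3, 2, 1))
        probs[:, 0, 0] = [0.2, 0.4, 0.6]
        probs[:, 1, 0] = [0.9, 0.9, 0.9]
        y = np.array([[0], [1]])
        s = probability_ranking(probs, y, 0, MiningConfig(top_n=5),
                                gene_ids=["gA", "gB"])
        (gene, avg, mn, mx), = s.ranked
        assert gene == "gA"
        assert (avg, mn, mx) == pytest.approx((0.4, 0.2, 0.6))

    def test_single_run_degenerate(self):
        probs = np.full((1, 3, 1), 0.3)
        y = np.zeros((3, 1), dtype=int)
        s = probability_ranking(probs, y, 0, MiningConfig(top_n=3))
        for _, avg, mn, mx in s.ranked:
            assert avg == mn == mx == pytest.approx(0.3)

    def test_percentile_interpolation_and_top1(self):
        n = 100
        avgs = np.full(n, 0.01)
        avgs[-1] = 0.9
        probs = np.tile(avgs[None, :, None], (2, 1, 1))
        y = np.zeros((n, 1), dtype=int)
        ids = [f"g{i:03d}" for i in range(n)]
        s = probability_ranking(probs, y, 0, MiningConfig(top_n=1, percentile=99),
                                gene_ids=ids)
        assert s.ranked[0][0] == "g099"
        assert s.percentile_value == pytest.approx(
            float(np.percentile(avgs, 99))
        )

    def test_restricted_to_recorded_negatives(self):
        probs = np.zeros((1, 4, 1))
        probs[0, :, 0] = [0.9, 0.8, 0.7, 0.6]
        y = np.array([[1], [0], [1], [0]])
        s = probability_ranking(probs, y, 0, MiningConfig(top_n=10),
                                gene_ids=["a", "b", "c", "d"])
        assert [g for g, *_ in s.ranked] == ["b", "d"]

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        probs = rng.random((4, 30, 2))
        y = rng.integers(0, 2, size=(30, 2))
        y[:3, 1] = 0
        ids = [f"g{i:02d}" for i in range(30)]
        s1 = probability_ranking(probs, y, 1, MiningConfig(), gene_ids=ids)
        perm = rng.permutation(30)
        s2 = probability_ranking(probs[:, perm], y[perm], 1, MiningConfig(),
                                 gene_ids=[ids[i] for i in perm])
        assert s1.ranked == s2.ranked
        assert s1.percentile_value == pytest.approx(s2.percentile_value)

    def test_no_negatives_rejected(self):
        probs = np.zeros((1, 3, 1))
        with pytest.raises(ValueError, match="negative"):
            probability_ranking(probs, np.ones((3, 1), dtype=int), 0,
                                MiningConfig())


@pytest.fixture(scope="module")
def mined():
    from modnn.candidate_mining import mine_candidates
    from modnn.networks import TrainConfig, train_encoders
    from modnn.synthetic import (
        BlockSpec,
        SyntheticConfig,
        generate_dataset,
        plant_negative_candidates,
    )

    cfg = SyntheticConfig(
        n_genes=500, n_classes=2, seed=23, prevalence=0.15,
        signal_strength=0.5, signal_features_per_class_per_block=12,
        label_correlation=0.5,
        block_specs=(BlockSpec("a", 40, 0.05), BlockSpec("b", 40, 0.05)),
    )
    ds, gt = generate_dataset(cfg)
    ds, gt = plant_negative_candidates(ds, gt, 0, 3, seed=1)
    tc = TrainConfig(max_epochs=25, seed=0)
    enc = train_encoders(ds, ds.gene_universe, tc)
    mc = MiningConfig(n_runs=4, min_run_support=3, seed=0)
    return ds, gt, mc, mine_candidates(ds, enc, [0], mc, tc)


class TestMiningAggregation:

    def test_record_invariants(self, mined):
        ds, _, mc, result = mined
        for recs in result.records.values():
            for r in recs:
                assert 0 < r.run_support <= mc.n_runs
                assert r.run_support >= mc.min_run_support
                assert r.min_prob <= r.avg_prob <= r.max_prob
                for g, (times, label) in r.neighbour_counts.items():
                    assert 1 <= times <= mc.n_runs
                    assert label in (0, 1)
                    assert g != r.gene

    def test_prob_runs_shape(self, mined):
        ds, _, mc, result = mined
        assert result.prob_runs.shape == (
            mc.n_runs, len(ds.gene_universe), ds.labels.n_classes
        )

    def test_raising_run_support_shrinks_candidates(self, mined):
        ds, _, mc, result = mined
        counts = {}
        for cname, recs in result.records.items():
            counts[cname] = {r.gene: r.run_support for r in recs}
        for cname, by_gene in counts.items():
            stricter = {g for g, s in by_gene.items() if s >= mc.n_runs}
            assert stricter <= set(by_gene)

    def test_report_export(self, mined, tmp_path):
        import json

        _, _, _, result = mined
        result.write(tmp_path)
        assert (tmp_path / "candidates.tsv").exists()
        doc = json.loads((tmp_path / "candidates.json").read_text())
        assert set(doc) == set(result.records)
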