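"""Mining candidate disease genes among the recorded negatives.

Negative labels in gene-disease data mean "no recorded association", not
"no association" — absence of evidence.  Two procedures interrogate a
trained modular model for negatives that look positive:

**Embedding-neighbourhood mining.**  Each gene's combiner last-hidden-layer
embedding is multiplied elementwise by the output-layer weight column of one
class, giving a class-specific projection.  A negative gene whose k = 10
nearest neighbours (Euclidean) in that space include at least 9 positives is
a candidate.  Because network training is stochastic, the combiner is
retrained ``n_runs`` times (default 30) with different seeds, encoders held
fixed, and only genes qualifying in at least ``min_run_support`` runs
(default 20) are reported, together with per-run probability summaries and a
neighbour frequency table.

**Probability ranking.**  Independently, the per-run predicted class
probabilities of every negative gene are averaged across runs; the top
``top_n`` negatives by average probability are reported next to the
``percentile`` (default 99th) percentile of those averages, to show how far
the top candidates stand above the bulk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import Dataset
from .networks import ModularModel, TrainConfig, TrainedNetwork, train_combiner, train_encoders
from .seeding import derive_seed

__all__ = [
    "MiningConfig",
    "CandidateRecord",
    "ProbabilitySummary",
    "MiningResult",
    "class_weighted_embeddings",
    "knn_negative_candidates",
    "mine_candidates",
    "probability_ranking",
]


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds of the two mining procedures."""

    knn_k: int = 10
    min_positive_neighbours: int = 9
    n_runs: int = 30
    min_run_support: int = 20
    percentile: float = 99.0
    top_n: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_positive_neighbours > self.knn_k:
            raise ValueError("min_positive_neighbours must be <= knn_k")
        if self.min_run_support > self.n_runs:
            raise ValueError("min_run_support must be <= n_runs")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0,100]")


@dataclass
class CandidateRecord:
    """One mined negative gene for one class."""

    gene: str
    class_name: str
    run_support: int
    avg_prob: float
    min_prob: float
    max_prob: float
    #: neighbour gene -> (times in the candidate's NN list across runs, label)
    neighbour_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class ProbabilitySummary:
    """Top negatives of one class by average predicted probability."""

    class_name: str
    percentile: float
    percentile_value: float
    #: (gene, avg, min, max), sorted by avg descending
    ranked: list[tuple[str, float, float, float]] = field(default_factory=list)


def class_weighted_embeddings(
    model: ModularModel, dataset: Dataset, class_id: int, genes: Sequence[str] | None = None
) -> np.ndarray:
    """Gene x d class-specific projection: combiner embedding scaled by the
    output-weight column of ``class_id``."""
    if not 0 <= class_id < len(model.class_names):
        raise IndexError(f"class_id {class_id} out of range")
    genes = list(dataset.gene_universe) if genes is None else list(genes)
    emb = model.combiner_embedding(dataset, genes)
    return emb * model.output_weights[:, class_id][None, :]


def knn_negative_candidates(
    projection: np.ndarray,
    labels: np.ndarray,
    class_id: int,
    cfg: MiningConfig,
    gene_ids: Sequence[str] | None = None,
) -> list[tuple[int, np.ndarray]]:
    """Negative genes with >= ``min_positive_neighbours`` positives among
    their ``knn_k`` nearest neighbours in the projection space.

    Distance is Euclidean; the gene itself is excluded; distance ties break
    by gene identifier order (gene index order when ids are absent).
    Returns (gene row index, neighbour row indices) pairs.
    """
    projection = np.asarray(projection, dtype=np.float64)
    n = projection.shape[0]
    if n < cfg.knn_k + 1:
        raise ValueError(f"need at least knn_k+1={cfg.knn_k + 1} genes, got {n}")
    y = np.asarray(labels)
    y = y[:, class_id] if y.ndim == 2 else y
    # identifier rank for deterministic tie-breaks
    if gene_ids is not None:
        id_rank = np.argsort(np.argsort(np.asarray(gene_ids)))
    else:
        id_rank = np.arange(n)

    sq = np.einsum("ij,ij->i", projection, projection)
    out: list[tuple[int, np.ndarray]] = []
    for i in np.flatnonzero(y == 0):
        d2 = sq + sq[i] - 2.0 * (projection @ projection[i])
        d2[i] = np.inf
        order = np.lexsort((id_rank, np.round(d2, 12)))
        nn = order[: cfg.knn_k]
        if int(y[nn].sum()) >= cfg.min_positive_neighbours:
            out.append((int(i), nn))
    return out


def mine_candidates(
    dataset: Dataset,
    encoders: dict[str, TrainedNetwork],
    class_ids: Sequence[int],
    cfg: MiningConfig,
    train_cfg: TrainConfig | None = None,
    genes: Sequence[str] | None = None,
    full_retrain: bool = False,
) -> "MiningResult":
    """Embedding-neighbourhood mining across ``cfg.n_runs`` randomized runs.

    The encoders are trained once by the caller and held fixed; each run
    retrains only the combiner with a run-derived seed (``full_retrain=True``
    retrains the encoders too), computes per-class weighted projections, and
    applies the k-NN test.  Candidates qualifying in at least
    ``min_run_support`` runs are reported with probability summaries over all
    runs and neighbour frequency tables.
    """
    train_cfg = train_cfg or TrainConfig()
    genes = list(dataset.gene_universe) if genes is None else list(genes)
    labels = dataset.labels.rows(genes)
    n, C = len(genes), dataset.labels.n_classes

    prob_runs = np.zeros((cfg.n_runs, n, C))
    qualify_counts = {c: np.zeros(n, dtype=int) for c in class_ids}
    neighbour_tallies: dict[int, dict[int, dict[int, int]]] = {
        c: {} for c in class_ids
    }

    for r in range(cfg.n_runs):
        run_seed = derive_seed(cfg.seed, "run", r)
        from dataclasses import replace

        run_cfg = replace(train_cfg, seed=run_seed)
        if full_retrain:
            run_encoders = train_encoders(dataset, genes, run_cfg,
                                          d_embed=next(iter(encoders.values())).spec.embed_dim)
        else:
            run_encoders = encoders
        model = train_combiner(dataset, run_encoders, genes, run_cfg)
        emb = model.combiner_embedding(dataset, genes)
        prob_runs[r] = model.combiner.predict_proba(model.encoder_embeddings(dataset, genes))
        for c in class_ids:
            proj = emb * model.output_weights[:, c][None, :]
            hits = knn_negative_candidates(proj, labels, c, cfg, gene_ids=genes)
            for gi, nn in hits:
                qualify_counts[c][gi] += 1
                tally = neighbour_tallies[c].setdefault(gi, {})
                for j in nn:
                    tally[int(j)] = tally.get(int(j), 0) + 1

    records: dict[str, list[CandidateRecord]] = {}
    for c in class_ids:
        cname = dataset.labels.class_names[c]
        recs = []
        for gi in np.flatnonzero(qualify_counts[c] >= cfg.min_run_support):
            probs = prob_runs[:, gi, c]
            tally = neighbour_tallies[c].get(int(gi), {})
            neigh = {
                genes[j]: (times, int(labels[j, c]))
                for j, times in sorted(tally.items(), key=lambda kv: (-kv[1], genes[kv[0]]))
            }
            recs.append(
                CandidateRecord(
                    gene=genes[int(gi)],
                    class_name=cname,
                    run_support=int(qualify_counts[c][gi]),
                    avg_prob=float(probs.mean()),
                    min_prob=float(probs.min()),
                    max_prob=float(probs.max()),
                    neighbour_counts=neigh,
                )
            )
        recs.sort(key=lambda r: (-r.run_support, r.gene))
        records[cname] = recs

    return MiningResult(records, prob_runs, genes, list(dataset.labels.class_names), cfg)


def probability_ranking(
    prob_runs: np.ndarray,
    labels: np.ndarray,
    class_id: int,
    cfg: MiningConfig,
    gene_ids: Sequence[str] | None = None,
    class_name: str | None = None,
) -> ProbabilitySummary:
    """Rank the negative genes of one class by run-averaged probability.

    ``prob_runs`` is (runs, genes, classes).  The percentile (linear
    interpolation) is taken over the averages of the negative genes; ties in
    the ranking break lexicographically on the gene identifier.
    """
    prob_runs = np.asarray(prob_runs, dtype=np.float64)
    if prob_runs.ndim != 3 or prob_runs.shape[0] < 1:
        raise ValueError("prob_runs must be (runs, genes, classes) with >= 1 run")
    y = np.asarray(labels)
    y = y[:, class_id] if y.ndim == 2 else y
    neg = np.flatnonzero(y == 0)
    if neg.size == 0:
        raise ValueError("no negative genes for this class")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(prob_runs.shape[1])]

    p = prob_runs[:, neg, class_id]
    avg, mn, mx = p.mean(axis=0), p.min(axis=0), p.max(axis=0)
    pct = float(np.percentile(avg, cfg.percentile))
    order = sorted(range(neg.size), key=lambda i: (-avg[i], gene_ids[neg[i]]))
    ranked = [
        (gene_ids[neg[i]], float(avg[i]), float(mn[i]), float(mx[i]))
        for i in order[: cfg.top_n]
    ]
    return ProbabilitySummary(
        class_name=class_name or f"class{class_id}",
        percentile=cfg.percentile,
        percentile_value=pct,
        ranked=ranked,
    )


@dataclass
class MiningResult:
    """Aggregate of an embedding-mining experiment across runs."""

    records: dict[str, list[CandidateRecord]]
    prob_runs: np.ndarray  # (runs, genes, classes)
    gene_ids: list[str]
    class_names: list[str]
    config: MiningConfig

    def probability_summary(self, class_id: int, labels: np.ndarray) -> ProbabilitySummary:
        return probability_ranking(
            self.prob_runs,
            labels,
            class_id,
            self.config,
            gene_ids=self.gene_ids,
            class_name=self.class_names[class_id],
        )

    def write(self, outdir: str | Path) -> None:
        """TSV + JSON reports mirroring the candidate and ranking tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        doc = {}
        for cname, recs in self.records.items():
            doc[cname] = []
            for r in recs:
                rows.append(
                    {
                        "class": cname,
                        "gene": r.gene,
                        "run_support": r.run_support,
                        "avg_prob": round(r.avg_prob, 4),
                        "min_prob": round(r.min_prob, 4),
                        "max_prob": round(r.max_prob, 4),
                    }
                )
                doc[cname].append(
                    {
                        "gene": r.gene,
                        "run_support": r.run_support,
                        "avg_prob": r.avg_prob,
                        "min_prob": r.min_prob,
                        "max_prob": r.max_prob,
                        "neighbours": [
                            {"gene": g, "times_in_nn_list": t, "label": lab}
                            for g, (t, lab) in r.neighbour_counts.items()
                        ],
                    }
                )
        pd.DataFrame(
            rows,
            columns=["class", "gene", "run_support", "avg_prob", "min_prob", "max_prob"],
        ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        (outdir / "candidates.json").write_text(json.dumps(doc, indent=1))
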