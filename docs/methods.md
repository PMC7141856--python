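# Methods

## The problem

Gene–disease association data is multi-label and multi-source: each human
gene may be annotated with several diseases (or none), and the evidence about
a gene is scattered over heterogeneous sources — GO-term annotations,
protein–protein interaction partners, pathway memberships, tissue expression.
Two properties of such data shape everything in this package:

* **missingness is structured** — a gene can be entirely absent from a source
  ("unknown" to that source), and the unknown genes are not a random subset;
* **negative labels are weak** — "not annotated with disease d" mostly means
  "never studied for d", so some recorded negatives are missed positives.

## The modular network

One **encoder** per feature source: a fully connected net with hidden layers
of 64, 32 and 16 rectified-linear units, dropout 0.5 on the hidden layers
during training, and a per-class sigmoid output head (multi-label; one output
per disease).  After an encoder is trained on its source's known genes, the
head is removed and the 16 activations of the last hidden layer become a
learned embedding of the gene.

The **combiner** — hidden layers of 32 and 16 units, no dropout — maps the
concatenated encoder embeddings to the final per-disease probabilities.
Encoders are frozen while the combiner trains.  A gene unknown to a source
feeds that encoder the zero vector, so its embedding is the encoder's
response to zero input and the modular model scores *every* gene: late
integration converts per-source missingness into full coverage.

Parameter counting for layer widths `[n0, ..., nL]` is `sum (n_i + 1) *
n_{i+1}` (one bias per unit).  The default encoder therefore has
`(n_feats+1)*64 + 3067` weights with its head, `(n_feats+1)*64 + 2608`
without.  The embedding width is configurable (`d_embed`, default 16); a
64-wide setting is also supported, under which a four-source combiner has a
256-wide input and `257*32 + 33*16 + 17*27 = 9211` weights for 27 classes.
Published descriptions of this architecture state the 16-wide embedding in
prose while printing weight totals consistent only with the 64-wide reading;
both are kept available and the arithmetic itself is what the tests pin down.

### Training

Minibatch SGD (default learning rate 0.01, momentum 0.9, batch 32) on the
mean per-class binary cross-entropy, with inverted dropout and early stopping
on a 10% validation split (patience 10, best weights restored).  The loss
choice is forced by the protocol: per-class sigmoid probabilities are what a
per-class AUROC can rank.  Everything is deterministic under the configured
seed; one experiment seed fans out into per-component seeds by hashing the
component's name (not its position), so model content is invariant to block
ordering and the randomized-runs protocol is reproducible.  The engine is a
compact numpy implementation — at desk scale (10^3–10^4 genes, 10^1–10^2
features per source) dense matmuls dominate and nothing heavier is needed.

### Forward sequential selection (FSS)

Training genes split 2/3 learning / 1/3 evaluation.  Encoders are trained
once on the learning set; module sets are scored by retraining the combiner
on the learning set and measuring macro-AUROC on the evaluation set.  The
best single module is always kept; further modules are added greedily while
the score improves by more than `improvement_epsilon` (default 0).  The
returned model is retrained on all training genes with the selected blocks.

## Evaluation protocol

k-fold cross-validation over genes (default 10; plain random, not
label-stratified — nothing in the protocol requires stratification, and rare
labels simply go undefined in some folds).  Per fold, each class's AUROC is
the Mann–Whitney statistic (midranks for ties); a class with no positives or
no negatives in the fold is *skipped* in that fold's macro average rather
than imputed 0.5 — imputation would drag every fold toward chance and dilute
real signal.  The overall score is the mean of per-fold macros; this
class-then-fold order is what makes paired per-fold vectors available to the
statistical comparison.

Single-source models cannot score unknown genes from data. Two strategies:

* `all_genes`: unknown validation genes receive the *training-split* class
  frequencies as scores (training split, not full data, to avoid leakage).
  Because unknown genes tend to have fewer positive labels, frequency-filling
  ranks them low and can inflate AUROC — the package keeps both strategies
  visible precisely so this artefact is measurable.
* `known_only`: unknown validation genes are dropped.

## Baselines

* **Naive popularity**: per-gene annotation count per source (0 if absent;
  presence indicator for the dense source; "combined" sums all sources), the
  same score for every class.  It quantifies how much apparent skill reduces
  to study-popularity bias.
* **Flat learners**: gradient-boosted trees (lightgbm) and L2 logistic
  regression at library defaults, one independent binary model per class,
  over one block or the concatenation.
* **Stacking**: per-block base learners; their class probabilities form an
  `n_blocks x C` meta-feature vector per gene; a meta-learner maps it to the
  final probabilities.  Meta-features for training genes come from 5-fold
  out-of-fold prediction inside the training split — resubstitution
  probabilities would hand the meta-learner leaked labels.  Genes unknown to
  a block contribute that block's training class frequencies.

## Statistical comparison

Paired per-fold macro-AUROC vectors are compared two ways.

**Wilcoxon signed-rank (NHST)**, two-sided, normal approximation without
continuity correction, zero differences dropped, midranks on ties.  At k=10
this variant has a floor of p = 0.0051 for ten concordant folds
(z = (0 − 27.5)/√96.25) and gives 0.0069 / 0.0093 when the smallest /
second-smallest rank defects — useful reference points when reading
comparison tables.  An exact-enumeration variant (floor 2/1024 at k=10) is
provided for cross-checking.

**Bayesian signed-rank with ROPE**: the Dirichlet-process construction — the
fold differences are augmented with a pseudo-observation at 0 carrying prior
weight s = 0.5; each Monte-Carlo draw samples Dirichlet weights and computes
the posterior mass of the Walsh averages (z_i + z_j)/2 falling left of,
inside, and right of the region of practical equivalence (|δ| ≤ 0.01 AUROC
by default).  The reported triple is the fraction of draws in which each
region carries the plurality of mass (50 000 draws by default; triples sum
to 1 exactly because they are counts).  The ROPE makes "no practical
difference" a positive finding rather than a failure to reject.

## Candidate-gene mining

Both procedures interrogate a model trained on *all* genes for recorded
negatives that look positive.

**Embedding-neighbourhood mining.**  Each gene's combiner last-hidden-layer
embedding is multiplied elementwise by the output-weight column of one class,
giving a class-specific projection.  A negative gene with ≥ 9 positives among
its 10 Euclidean nearest neighbours (self excluded; distance ties broken by
gene identifier for determinism) is a per-run candidate.  Because training is
stochastic, the combiner is retrained `n_runs` times (default 30) from
different seeds — encoders fixed, matching the architecture's
add-a-source-retrain-only-the-combiner workflow; `full_retrain=True` retrains
encoders too — and only genes qualifying in ≥ `min_run_support` runs (default
20) are reported, with probability summaries across all runs and neighbour
frequency tables.  Per-run projections (not run-averaged ones) feed the k-NN
test, since the run-support filter is defined over per-run events.

**Probability ranking.**  Per class, negative genes are ranked by their
predicted class probability averaged across the runs; the report shows the
top 5 with min/max, next to the 99th percentile (linear interpolation) of the
averages over *negative* genes — the percentile population matches the ranked
population, so the quoted gap is internally consistent (a flag switches to
all genes).

## The synthetic generator

Real data for this problem cannot ship with a package; the generator emulates
the statistical structure the method actually exploits, and nothing else:

* per-class labels at configurable prevalence (default 0.1), with optional
  co-occurrence via a shared latent Bernoulli factor per consecutive class
  pair — the simplest mechanism with controllable overlap, mirroring the fact
  that age-related diseases share associated genes;
* sparse binary blocks at background rate 0.01 (annotation matrices are
  ~1% dense); per class and block, a set of *signal features* whose
  activation probability is lifted by `signal_strength` in positive genes;
  a dense block with log-normal background and mean-shifted signal features;
* per-block unknown genes at configurable fractions (defaults 4.0 / 19.4 /
  16.8 / 4.1%, the profile of a real four-source compilation), with repair
  so every gene stays known somewhere;
* popularity bias: genes with any positive label get their background
  annotation rate multiplied by (1 + `popularity_bias`) — exactly the
  confound the naive classifier exploits;
* planted mislabelled negatives: `plant_negative_candidates` flips recorded
  positives to 0, features untouched, and logs them for recovery scoring.

Not emulated: GO hierarchy, interaction-network topology, tissue covariance,
realistic feature dimensionality.  Passing tests therefore demonstrate that
the machinery is correct and that each claimed effect appears when its cause
is planted — not that real-data AUROC levels would be reproduced.

## Test-scale choices

The test and acceptance experiments run at desk scale, chosen once as the
package's own study conditions:

* null calibration: 1000 genes, 6 classes, 3 folds, 3 seeds — every method's
  macro-AUROC within 0.5 ± 0.03;
* integration benefit: 2000 genes, 4 classes, signal 0.3 split across four
  sources (10 signal features/class/block), 3 folds, 3 seeds — the modular
  model beats the best single source by ≥ 0.02 macro-AUROC;
* naive behaviour: 2000 genes, popularity bias 1 vs 0 — above 0.55 vs within
  0.5 ± 0.02 (3-seed means);
* planted recovery: 4000 genes, 4 classes, signal 0.4 with 20 signal
  features/class/block, label correlation 0.5, 5 planted genes, 10 runs with
  support threshold 7 — ≥ 80% of planted genes recovered (3-seed mean).

The recovery experiment's conditions are the interesting ones.  Three
features are load-bearing, each for a mechanistic reason: *enough signal
features per class* that a randomly chosen positive almost surely carries
measurable signal (with few signal features, a "positive" can draw an
uninformative feature vector and is unrecoverable in principle); *label
correlation*, so a flipped gene usually remains positive for a correlated
class, anchoring it in the positive embedding region — the multi-label
situation real mined candidates are in; and *enough genes* that the encoders
cannot memorize individual flipped genes via their idiosyncratic background
annotations (at 2000 genes the encoders pin some planted genes in the
negative region across all runs; at 4000 they cannot).  Recovery is stable
(mean 0.93, minimum 0.8 over six seeds) under these conditions.

## Numerical notes and limitations

* AUROC is rank-based; scores only matter up to monotone transforms.
* k-NN distance ties are resolved by identifier order after rounding squared
  distances to 12 decimals, so bit-level float noise cannot reorder
  neighbours between platforms.
* Single-class training columns (a disease with all-0 or all-1 labels in a
  split) make flat learners fall back to a constant predictor; networks
  handle them natively through the sigmoid loss.
* The engine is CPU-only and desk-scale by design; no GPU path, no
  convolutional/recurrent variants, no hyperparameter search.
* FSS scores candidate modules on a single learn/eval split, so its
  selections inherit that split's noise — observed occasionally as selecting
  a second, uninformative module on null data.
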