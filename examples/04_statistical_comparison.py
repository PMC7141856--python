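"""Compare paired per-fold AUROC vectors: Bayesian signed-rank with ROPE
plus the frequentist Wilcoxon signed-rank test.

The Bayesian test reports a probability triple: reference better /
practically equivalent (|difference| < 0.01 AUROC) / baseline better.
"""

import numpy as np

from modnn.stats_compare import ComparisonConfig, comparison_table, wilcoxon_p

# per-fold macro-AUROC vectors of a 10-fold experiment (reference clearly
# ahead of two baselines, neck-and-neck with a third)
rng = np.random.default_rng(0)
reference = 0.88 + rng.normal(0, 0.01, 10)
baselines = {
    "single_source": reference - 0.12 + rng.normal(0, 0.01, 10),
    "concatenated": reference - 0.03 + rng.normal(0, 0.005, 10),
    "strong_rival": reference + rng.normal(0, 0.003, 10),
}

cfg = ComparisonConfig(rope_halfwidth=0.01, mc_samples=50_000, seed=0)
table = comparison_table("modular", reference, baselines, cfg)
print(table.round(4).to_string(index=False))
# bayes_p_reference ~ 1 and nhst_p ~ 0.005 for the clearly-beaten baselines;
# the rival's mass concentrates in the ROPE column instead: "no practical
# difference" is a conclusion the NHST p-value alone cannot express

print("\nfloor of the k=10 normal-approximation test:",
      round(wilcoxon_p(reference, reference - np.linspace(0.05, 0.14, 10)), 4))
# 0.0051 -- ten concordant folds of distinct magnitude; the smallest p this
# variant can produce
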