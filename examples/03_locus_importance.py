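"""Shapley locus importance across a Pareto front.

Evolves a small front on additive data with decaying effect sizes and
aggregates per-locus Shapley importances (mean absolute Shapley value over
test samples, averaged across front pipelines with standard errors). Weakly
contributing loci fall to the bottom of the ranking; loci removed by a
pipeline's selectors contribute exact zeros to its column.
"""

import numpy as np

from evoqtl.data import split_data
from evoqtl.engine import GPConfig, evolve
from evoqtl.importance import aggregate_importance
from evoqtl.simulate import SimConfig, simulate_additive_phenotype, simulate_hwe_genotypes

X = simulate_hwe_genotypes(SimConfig(n_samples=600, n_loci=8, maf=0.3, seed=1))
betas = np.linspace(1.6, 0.2, 8)  # locus L01 strongest, L08 weakest
y = simulate_additive_phenotype(X, betas, noise_sd=2.0, seed=2)
split = split_data(600, seed=1)

archive, _ = evolve(X, y, split, GPConfig(population_size=15, offspring_size=15,
                                          generations=6, seed=1))
table = aggregate_importance(archive, X, y, split, seed=1, n_permutations=32)

print(f"front pipelines scored: {len(table.scores)}")
print(table.ranking().to_string(float_format=lambda v: f"{v:.4f}"))
print()
print("'mean' is the phenotype-unit Shapley importance averaged over the")
print("front; 'sem' its standard error across pipelines. Simulated effects")
print("decay from L01 to L08; weak loci land at the bottom, but the top ranks")
print("reflect the front's re-encodings and selections, not raw effect size -")
print("a locus favored by many pipelines accumulates importance, one removed")
print("by selectors contributes zeros.")
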