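"""Detecting pure two-locus epistasis that linear regression cannot see.

Builds a dataset whose only signal is nine XOR interactions (no marginal
effects at any locus, calibrated so a reference random forest detects test
R2 ~ 0.10), then evolves pipelines. Tree-based roots should dominate the
final Pareto front and out-score every LR-rooted pipeline.
"""

from evoqtl.data import baseline_multiple_lr_r2, split_data
from evoqtl.engine import GPConfig, evolve, summarize_front
from evoqtl.experiments import make_xor_dataset

X, y, pairs, achieved = make_xor_dataset(seed=0, n_samples=1000, n_loci=18, n_pairs=9)
split = split_data(X.n_samples, seed=0)

print(f"calibrated RF-detectable R2  : {achieved:.4f}")
print(f"multiple-LR R2 (full data)   : {baseline_multiple_lr_r2(X, y):.4f}")

archive, _ = evolve(X, y, split, GPConfig(population_size=20, offspring_size=20,
                                          generations=10, seed=0))
summary = summarize_front(archive)
ml = [f.test_r2 for t, f in archive if t.root.kind in ("DT", "RF")]
lr = [f.test_r2 for t, f in archive if t.root.kind == "LR"]

print(f"archive size                 : {summary.n_pipelines}")
print(f"ML-rooted share              : "
      f"{summary.root_percent.get('RF', 0) + summary.root_percent.get('DT', 0):.0f}%")
print(f"best ML test R2              : {max(ml, default=float('nan')):.4f}")
print(f"best LR test R2              : {max(lr, default=float('nan')) if lr else float('nan')}")
print(f"2-level final encodings      : {summary.encoding_percent.get('2-level', 0):.0f}%")
print()
print("LR sees essentially nothing (R2 ~ 0) while tree regressors capture the")
print("interaction variance - the signature of epistasis in the front.")
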