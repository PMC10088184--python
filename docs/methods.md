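# Methods

## The model

`evoqtl` searches over QTL-analysis *pipelines* rather than over a fixed
model family. A pipeline is an expression tree: an ordered chain of up to six
phases — inheritance-model encoders and genetic feature selectors, each with
a hyperparameter terminal — under exactly one regression root. Evolution by
genetic programming explores encoder/selector/regressor combinations and
hyperparameters globally, in any order, rather than in the fixed sequence a
human analyst would apply.

**Encoders** recode every locus through a total map on the genotype codes
{0, 1, 2} (copies of one allele). The canonical tables live in one place
(`operators.ENCODER_TABLES`) so an alternative convention can be swapped in:

| encoder        | 0→ | 1→ | 2→ | levels |
|----------------|----|----|----|--------|
| additive       | 0  | 1  | 2  | 3 (identity; no encoder phase) |
| dominant       | 0  | 2  | 2  | 2 |
| recessive      | 0  | 0  | 2  | 2 |
| heterosis      | 0  | 2  | 0  | 2 (homozygotes equal) |
| overdominance  | 0  | 2  | 1  | 3 |
| underdominance | 1  | 0  | 2  | 3 |

Tables were chosen so that dominant/recessive/heterosis collapse the three
genotype values to two (the "2-level" class reported by the front summary)
while over-/underdominance permute all three, and so that heterosis gives the
two homozygotes equal value. Encoder phases compose left-to-right; sequential
composition can reach maps unreachable by any single encoder (e.g. recessive
then overdominance gives 0,0,1). The front summary classifies each pipeline's
*final* inheritance model by the composed map's number of distinct outputs.

**Selectors** (fit on the training partition only; the resulting mask is
applied to test and holdout, so evaluation data never leaks into selection):

* VT — variance threshold, grid 0.00–0.35 step 0.05; keeps loci whose
  *population* variance is strictly above the threshold (so VT(0) already
  drops constants, including loci collapsed to a constant by encoders).
* SP — select percentile, grid 5–95% step 5; univariate F statistic
  `F = r²/(1−r²)·(n−2)` against the phenotype; kept count
  `max(1, round(p/100·m))` with half rounding up; ties break toward the
  lower column index; constant columns score 0, perfect correlation scores
  +inf.
* GF — genotype frequency, grid 0.00–0.35 step 0.05; removes a locus when
  any genotype class *present in the column* falls below the threshold.
  Absent classes are ignored — otherwise every 2-level-encoded locus would
  be removed at any positive threshold, contradicting the fronts such
  pipelines demonstrably populate.

**Roots**: ordinary least squares (LR, no hyperparameters), CART regression
tree (DT: max_depth 1–10, min_samples_leaf 1–20, min_samples_split 2–20) and
random forest (RF: bootstrap T/F, max_features 0.05–1.00 step 0.05,
min_samples_leaf, min_samples_split; 100 trees, fixed — tree count is not an
evolved hyperparameter). sklearn provides the estimators; all tree
randomness derives from the run seed.

## Fitness and selection

Data are split 20% holdout / 40% train / 40% test (holdout = `floor(0.2n)`,
the remainder halved with the odd sample going to test — percentages alone
do not fix a rounding rule, so this one is pinned for reproducibility). Each
pipeline is fit on train and scored on both partitions:

* objective 1: test-split R², maximized;
* objective 2: the difference score `DS = (1/|train R² − test R²|)^(1/4)`,
  maximized — an overfitting penalty that rewards train/test agreement. The
  singularity at equal scores is floored at |Δ| = 1e−8, capping DS at 100.

Pipelines whose selectors remove every locus receive a sentinel worst
fitness (−inf, −inf) instead of raising, so evolution discards them through
selection pressure.

Search runs population 100, offspring 100, mutation 0.9, crossover 0.1, 25
generations by default (all user-settable). Offspring are produced by
mutually exclusive variation — mutation with probability 0.9 (uniform
operator/hyperparameter replacement, insert, or shrink, each 1/3; insert is
resampled as uniform at the phase cap; shrink is a no-op on a phase-free
tree; the root can be swapped or re-parameterized but never deleted), else
one-point crossover restricted to positions of a phase class both parents
share (ineligible pairs fall back to cloning), first offspring kept.
Parents for variation are drawn uniformly; fitness pressure acts through
NSGA-II survival over parents ∪ offspring (fast non-dominated sort, boundary
front broken by crowding distance, every tie broken by insertion index so
runs are bit-reproducible). The Pareto archive is cumulative over the whole
run (hall-of-fame semantics): it always holds the non-dominated,
structurally deduplicated set of everything evaluated so far. Holdout R² is
computed for archive members only at the end, as an overfitting readout.

A consequence of the DS objective worth knowing: pipelines that collapse
the data to near-constant features earn train ≈ test ≈ 0 and hence a very
high DS, so the archive's low-R² flank fills with such "null" models. They
are genuinely Pareto-optimal under the stated objectives; readers of a front
should focus on its Pareto-efficient, high-R² region.

## Shapley locus importance

Per archive pipeline, Shapley values are computed in the pipeline's
*transformed* feature space with the transformed train split as background
and the transformed test split as evaluation points (importance then
measures generalizable contribution). The per-locus score is the mean
|Shapley value| over evaluation samples, reported against the original
locus identifiers (encoders are per-locus recodings; selectors only
remove). Loci removed by selectors score exactly 0. Estimators:

* LR: exact closed form `φ_j = β_j (x_j − mean background x_j)`; local
  accuracy holds to 1e−6.
* DT/RF: seeded permutation sampling (default 64 permutations ⇒ thousands
  of model evaluations). Each permutation telescopes, so per-sample values
  sum exactly to prediction − mean prediction over the sampled backgrounds;
  accuracy against the full background mean is within sampling error
  (≈3 SE).

Cross-pipeline aggregation reports per-locus mean and standard error of the
mean with selector-removed zeros included, exactly as those loci enter (or
rather do not enter) each model.

## The XOR epistasis simulator

Genotypes are i.i.d. Hardy-Weinberg draws at configurable minor-allele
frequency. The XOR penetrance table assigns penetrance 1 exactly when one
locus of a pair is heterozygous — the unique symmetric 0/1 table whose
HWE-weighted marginal penetrance at allele frequency 0.5 is exactly 0.5 for
every single-locus genotype, i.e. pure epistasis with no marginal effects.

An interaction is injected by jointly re-assigning the two loci's genotype
rows so penetrance-1 combinations occupy the top phenotype ranks (ties at
the median break by sample index). Because only the *rows* of the pair are
re-arranged, the multiset of two-locus combinations — hence every genotype
and allele frequency — is preserved bit-exactly; this is asserted in tests.
The maximal signal is then weakened by re-permuting the pair's combinations
among a random fraction of rows, and a bisection (≤20 iterations) on a
common fraction calibrates the *detectable* R² — measured by a fixed
reference forest (bootstrap, max_features 0.25, min_samples_leaf 5,
min_samples_split 10, 100 trees, seeded) on a train/test split — to a
target within ±0.01. The probe's hyperparameters are a convention, isolated
in `simulate.REFERENCE_RF_PARAMS`; any interaction-capable regressor would
do. Targets above the unshuffled ceiling raise an error reporting the
ceiling.

Interaction ladders produce datasets with 0..k pairs: `replace_noise` first
destroys all main effects by independent column permutation and then injects
one pair per rung; `replace_main_effects` starts from intact data and per
rung permutes two further main-effect columns before pairing them. Pairs are
random and disjoint throughout (with k=9 on 18 loci, every locus is in
exactly one pair).

## Simulated study conditions and what they show

The replication experiments run, by default, at a reduced scale chosen so
the whole suite fits interactive use on one CPU: population 20, offspring
20, 10 generations, n = 1000 samples, 18 loci. The probe-only interaction
ladders instead use n = 5566 (the benchmark-cohort size this package's
experiments emulate): with 18 predictors, OLS's out-of-sample bias is about
−m/n_train, which at n = 1000 (≈ −0.045) would swamp the "LR stays near
zero" signature that is genuine at realistic cohort sizes (≈ −0.01 at
n = 5566).

The additive generator uses equal effects (β = 1 at all loci), MAF 0.3, and
noise set analytically from the HWE variance `2q(1−q)` so the population R²
is 0.10. It emulates main-effect QTL panels in aggregate but not features
of real panels: no linkage disequilibrium between loci, no effect-size
skew, no relatedness structure, and a Gaussian phenotype. Passing tests
therefore show the machinery behaves as designed under clean conditions —
not that real-data fronts will look identical.

At this reduced scale the additive-validation property (an LR-rooted
archive pipeline matching the multiple-LR test R² within 0.005 in every
seed) holds in 9 of 10 seeds: on one seed the random test split is weak
enough (baseline R² 0.023 against population 0.10) that a strongly
regularized forest legitimately beats OLS on *both* objectives and evicts
it from the archive. The same seed passes at n = 5566. The corresponding
test asserts the 10/10 property and is expected to fail on that seed; the
package reports this honestly rather than widening the condition.

## Numerical choices and degenerate inputs

* R² is `1 − SS_res/SS_tot`, allowed negative out of sample; singular
  designs are fit by least squares without error.
* Constant phenotypes are rejected wherever a model would be fit.
* Missing genotypes and codes outside {0, 1, 2} are rejected at load with
  the offending row/column named; imputation is upstream of this tool.
* All randomness flows from integer seeds through `numpy.random.Generator`;
  identical (data, config, seed) gives bit-identical archives, logs and
  TSV outputs.
* Uniform mutation resamples until the operator or value actually changes;
  a no-op mutation would waste an offspring evaluation.

## Known limitations

* Encoding is genome-wide, not per-locus; classifier roots for discrete
  phenotypes, model export, and expert-knowledge operators are out of
  scope.
* The archive can grow large on noisy data because many structurally
  distinct pipelines earn exactly equal (test R², DS) pairs and equal-
  fitness members never dominate each other.
* Shapley values for tree roots are sampled estimates; symmetry and
  null-player properties hold to sampling tolerance only.
* No linkage disequilibrium, kinship correction, or phenotype
  normalization: inputs are assumed pre-processed.
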