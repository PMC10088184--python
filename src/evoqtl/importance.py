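"""Shapley-value locus importance for Pareto-front pipelines.

Each locus's contribution to a pipeline's predictions is attributed with
Shapley values computed in the pipeline's transformed feature space
(background distribution = transformed train split, evaluation points =
transformed test split), then reported against the ORIGINAL locus
identifiers — encoders are per-locus recodings and selectors only remove
columns, so the column-to-locus correspondence is preserved. A locus removed
by a pipeline's selectors contributes nothing to that model and scores
exactly 0.

Two estimators: the exact closed form for linear models (phi_j = beta_j *
(x_j - mean background x_j), satisfying local accuracy to machine precision)
and a seeded permutation-sampling estimator for tree models (each sampled
permutation telescopes, so per-sample Shapley values still sum exactly to
prediction minus the mean prediction over the sampled backgrounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ParetoArchive
from .operators import fit_regressor
from .pipeline import PipelineTree, execute_pipeline

__all__ = [
    "shapley_linear",
    "shapley_sampling",
    "pipeline_shapley",
    "ImportanceTable",
    "aggregate_importance",
    "importance_delta",
]


def shapley_linear(model, X_background, X_eval) -> np.ndarray:
    """Exact Shapley values for a fitted linear model, one row per sample."""
    X_background = np.asarray(X_background, dtype=float)
    X_eval = np.asarray(X_eval, dtype=float)
    return model.coef_ * (X_eval - X_background.mean(axis=0))


def shapley_sampling(predict, X_background, X_eval, rng,
                     n_permutations: int = 64) -> np.ndarray:
    """Permutation-sampling Shapley estimate for an arbitrary model.

    For each sampled permutation a background row is drawn and features are
    switched from background to evaluation values one at a time; the marginal
    prediction changes are the sampled contributions. Per evaluation sample
    the estimate sums exactly to prediction(x) minus the mean prediction over
    the sampled background rows.
    """
    X_background = np.asarray(X_background, dtype=float)
    X_eval = np.asarray(X_eval, dtype=float)
    n_eval, m = X_eval.shape
    phi = np.zeros((n_eval, m))
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        z = X_background[int(rng.integers(len(X_background)))]
        current = np.tile(z, (n_eval, 1))
        prev = np.asarray(predict(current), dtype=float)
        for j in perm:
            current[:, j] = X_eval[:, j]
            nxt = np.asarray(predict(current), dtype=float)
            phi[:, j] += nxt - prev
            prev = nxt
    return phi / n_permutations


def pipeline_shapley(tree: PipelineTree, X, y, split, seed: int,
                     n_permutations: int = 64) -> np.ndarray:
    """Per-locus importance of one pipeline: mean |Shapley| over test samples.

    Scores are aligned to the original loci; selector-removed loci are
    exactly 0.
    """
    codes = np.asarray(getattr(X, "codes", X))
    y = np.asarray(y, dtype=float)
    tr, te = split.train_idx, split.test_idx
    Xtr, Xte, mask = execute_pipeline(tree, codes[tr], codes[te], y_train=y[tr])
    model = fit_regressor(tree.root, Xtr, y[tr], seed=seed)
    if tree.root.kind == "LR":
        phi = shapley_linear(model, Xtr, Xte)
    else:
        rng = np.random.default_rng(seed)
        phi = shapley_sampling(model.predict, Xtr, Xte, rng, n_permutations=n_permutations)
    scores = np.zeros(codes.shape[1])
    scores[mask] = np.abs(phi).mean(axis=0)
    return scores


@dataclass
class ImportanceTable:
    """Per-pipeline locus scores with cross-pipeline mean and SEM."""

    scores: pd.DataFrame  # rows = pipelines, columns = locus ids
    mean: pd.Series
    sem: pd.Series

    def ranking(self) -> pd.DataFrame:
        out = pd.DataFrame({"mean": self.mean, "sem": self.sem})
        out["rank"] = out["mean"].rank(ascending=False, method="first").astype(int)
        return out.sort_values("rank")


def aggregate_importance(archive: ParetoArchive, X, y, split, seed: int,
                         n_permutations: int = 64) -> ImportanceTable:
    """Mean and standard error of locus importance across the Pareto front.

    Zeros from selector-removed loci are included in the averages, exactly as
    they enter each pipeline's model (with no contribution).
    """
    if len(archive) == 0:
        raise ValueError("archive is empty; nothing to score")
    locus_ids = list(getattr(X, "locus_ids", range(np.asarray(getattr(X, "codes", X)).shape[1])))
    rows, labels = [], []
    for i, (tree, _) in enumerate(archive):
        rows.append(pipeline_shapley(tree, X, y, split, seed=seed, n_permutations=n_permutations))
        labels.append(f"{i}: {tree.describe()}")
    scores = pd.DataFrame(np.vstack(rows), index=labels, columns=locus_ids)
    mean = scores.mean(axis=0)
    if len(scores) > 1:
        sem = scores.std(axis=0, ddof=1) / np.sqrt(len(scores))
    else:
        sem = pd.Series(0.0, index=scores.columns)
    return ImportanceTable(scores=scores, mean=mean, sem=sem)


def importance_delta(before: ImportanceTable, after: ImportanceTable, pairs) -> pd.DataFrame:
    """|mean importance difference| within each locus pair, before vs after.

    Used to ask whether two loci's importances converge once their main
    effects are replaced by a shared interaction.
    """
    if set(before.mean.index) != set(after.mean.index):
        raise ValueError("importance tables cover different locus sets")
    rows = []
    for a, b in pairs:
        for locus in (a, b):
            if locus not in before.mean.index:
                raise ValueError(f"locus {locus!r} not present in the importance tables")
        rows.append(
            {
                "locus_a": a,
                "locus_b": b,
                "delta_before": abs(before.mean[a] - before.mean[b]),
                "delta_after": abs(after.mean[a] - after.mean[b]),
            }
        )
    return pd.DataFrame(rows)
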