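"""Replication experiments at reduced (desk) or full scale.

Four experiments mirror the study design around the method:

* ``validate`` — pure-additive simulated data; the final Pareto front should
  contain a linear-regression-only pipeline that recovers the multiple-LR
  test R2 of its split.
* ``xor9`` — nine pure XOR interactions, no main effects; machine-learning
  roots (RF/DT) should outnumber and out-score LR roots.
* ``ladder-noise`` / ``ladder-main`` — interaction ladders (0..9 pairs)
  probed with the reference RF and plain LR: RF-detectable R2 should climb
  with the interaction count while LR stays near zero (ladder-noise) or
  decays as main effects are consumed (ladder-main).

Reduced scale (population 20, offspring 20, 10 generations, n = 1000,
18 loci) runs the GP experiments in minutes on one CPU; full scale uses the
published run parameters (100/100/25 generations). Ladders are probe-only
and simulated at the benchmark cohort size n = 5566.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import GenotypeMatrix, baseline_multiple_lr_r2, split_data
from .engine import GPConfig, evolve, summarize_front
from .simulate import (
    InteractionPlan,
    SimConfig,
    additive_noise_sd_for_target_r2,
    build_interaction_ladder,
    calibrate_to_target_r2,
    detectable_r2,
    inject_xor_pairs,
    simulate_additive_phenotype,
    simulate_hwe_genotypes,
)

__all__ = [
    "REDUCED_SCALE",
    "FULL_SCALE",
    "make_additive_dataset",
    "make_xor_dataset",
    "run_validation_experiment",
    "run_xor_experiment",
    "run_ladder_experiment",
    "run_experiment",
]

REDUCED_SCALE = dict(population=20, offspring=20, generations=10, n_samples=1000, n_loci=18)
FULL_SCALE = dict(population=100, offspring=100, generations=25, n_samples=5566, n_loci=18)
#: Cohort size for the probe-only interaction ladders.
LADDER_N = 5566


def make_additive_dataset(seed: int, n_samples: int = 1000, n_loci: int = 18,
                          maf: float = 0.3, target_r2: float = 0.10):
    """HWE genotypes with equal additive effects and noise set analytically
    so the population R2 of the full additive model equals ``target_r2``."""
    X = simulate_hwe_genotypes(SimConfig(n_samples=n_samples, n_loci=n_loci, maf=maf, seed=seed))
    betas = np.ones(n_loci)
    noise_sd = additive_noise_sd_for_target_r2(betas, maf, target_r2)
    y = simulate_additive_phenotype(X, betas, noise_sd, seed=seed + 1)
    return X, y


def make_xor_dataset(seed: int, n_samples: int = 1000, n_loci: int = 18,
                     n_pairs: int = 9, target_r2: float = 0.10):
    """Pure-epistasis dataset: standard-normal phenotype, ``n_pairs`` XOR
    interactions injected and shuffled down to the target detectable R2.

    Returns ``(X, y, pairs, achieved_r2)``.
    """
    X = simulate_hwe_genotypes(SimConfig(n_samples=n_samples, n_loci=n_loci, maf=0.5, seed=seed))
    y = np.random.default_rng(seed + 1).normal(size=n_samples)
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(n_loci)
    pairs = tuple((int(order[2 * i]), int(order[2 * i + 1])) for i in range(n_pairs))
    X = inject_xor_pairs(X, y, pairs, seed=seed + 3)
    plan = InteractionPlan(pairs=pairs, target_r2=target_r2, seed=seed + 4)
    X, achieved = calibrate_to_target_r2(X, y, plan)
    return X, y, pairs, achieved


@dataclass
class GPExperimentResult:
    per_seed: pd.DataFrame
    fronts: list  # (archive, log) per seed


def _gp_config(seed: int, scale: dict) -> GPConfig:
    return GPConfig(
        population_size=scale["population"],
        offspring_size=scale["offspring"],
        generations=scale["generations"],
        seed=seed,
    )


def run_validation_experiment(seeds, scale: dict | None = None,
                              dataset: tuple | None = None) -> GPExperimentResult:
    """Per seed: does the final front hold an LR-rooted pipeline matching the
    multiple-LR baseline test R2 (within 0.005, one-sided)?

    ``dataset`` overrides the simulated additive data (e.g. real genotypes).
    """
    scale = scale or REDUCED_SCALE
    rows, fronts = [], []
    for seed in seeds:
        if dataset is None:
            X, y = make_additive_dataset(seed, n_samples=scale["n_samples"], n_loci=scale["n_loci"])
        else:
            X, y = dataset
        split = split_data(X.n_samples if isinstance(X, GenotypeMatrix) else len(y), seed)
        baseline = baseline_multiple_lr_r2(X, y, split, partition="test")
        archive, log = evolve(X, y, split, _gp_config(seed, scale))
        summary = summarize_front(archive)
        lr_scores = [f.test_r2 for t, f in archive if t.root.kind == "LR"]
        best_lr = max(lr_scores, default=float("-inf"))
        rows.append(
            {
                "seed": seed,
                "baseline_test_r2": baseline,
                "best_lr_test_r2": best_lr,
                "matches_baseline": best_lr >= baseline - 0.005,
                "archive_size": len(archive),
                "pct_lr": summary.root_percent.get("LR", 0.0),
                "last_improvement": log.last_improvement,
            }
        )
        fronts.append((archive, log))
    return GPExperimentResult(per_seed=pd.DataFrame(rows), fronts=fronts)


def run_xor_experiment(seeds, scale: dict | None = None,
                       dataset: tuple | None = None) -> GPExperimentResult:
    """Per seed: regressor census and best test R2 per root class on the
    nine-XOR pure-epistasis dataset."""
    scale = scale or REDUCED_SCALE
    rows, fronts = [], []
    for seed in seeds:
        if dataset is None:
            X, y, _, achieved = make_xor_dataset(
                seed, n_samples=scale["n_samples"], n_loci=scale["n_loci"]
            )
        else:
            X, y = dataset
            achieved = float("nan")
        split = split_data(len(y), seed)
        archive, log = evolve(X, y, split, _gp_config(seed, scale))
        summary = summarize_front(archive)
        ml = [f.test_r2 for t, f in archive if t.root.kind in ("DT", "RF")]
        lr = [f.test_r2 for t, f in archive if t.root.kind == "LR"]
        pct_ml = summary.root_percent.get("RF", 0.0) + summary.root_percent.get("DT", 0.0)
        rows.append(
            {
                "seed": seed,
                "calibrated_r2": achieved,
                "archive_size": len(archive),
                "pct_ml": pct_ml,
                "pct_lr": summary.root_percent.get("LR", 0.0),
                "max_ml_test_r2": max(ml, default=float("-inf")),
                "max_lr_test_r2": max(lr, default=float("-inf")),
                "ml_beats_lr": max(ml, default=float("-inf")) > max(lr, default=float("-inf")),
                "pct_2level": summary.encoding_percent.get("2-level", 0.0),
                "last_improvement": log.last_improvement,
            }
        )
        fronts.append((archive, log))
    return GPExperimentResult(per_seed=pd.DataFrame(rows), fronts=fronts)


def run_ladder_experiment(mode: str, seeds, k: int = 9, n_samples: int = LADDER_N,
                          n_loci: int = 18) -> pd.DataFrame:
    """Probe R2 (reference RF and plain LR) along a 0..k interaction ladder.

    ``mode`` is ``replace_noise`` (start from all-permuted columns) or
    ``replace_main_effects`` (consume two main-effect loci per rung). One row
    per (seed, rung).
    """
    rows = []
    for seed in seeds:
        X, y = make_additive_dataset(seed, n_samples=n_samples, n_loci=n_loci, maf=0.5)
        ladder = build_interaction_ladder(X, y, k=k, mode=mode, seed=seed + 5)
        for rung, Xk in enumerate(ladder.datasets):
            rows.append(
                {
                    "seed": seed,
                    "n_interactions": rung,
                    "rf_r2": detectable_r2(Xk, y, seed=seed, regressor="rf"),
                    "lr_r2": detectable_r2(Xk, y, seed=seed, regressor="lr"),
                }
            )
    return pd.DataFrame(rows)


def ladder_trend(curves: pd.DataFrame) -> dict:
    """Spearman trend of the mean RF probe R2 against interaction count."""
    means = curves.groupby("n_interactions")[["rf_r2", "lr_r2"]].mean()
    rho, _ = spearmanr(means.index, means["rf_r2"])
    return {
        "spearman_rho_rf": float(rho),
        "max_abs_lr_r2": float(means["lr_r2"].abs().max()),
        "means": means,
    }


def run_experiment(name: str, seeds, scale: dict | None = None):
    """Dispatch by experiment name: validate, xor9, ladder-noise, ladder-main."""
    if name == "validate":
        return run_validation_experiment(seeds, scale)
    if name == "xor9":
        return run_xor_experiment(seeds, scale)
    if name == "ladder-noise":
        return run_ladder_experiment("replace_noise", seeds)
    if name == "ladder-main":
        return run_ladder_experiment("replace_main_effects", seeds)
    raise ValueError(f"unknown experiment {name!r}")
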