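"""Genetic-programming search over pipeline trees under two-objective
Pareto optimization.

Each pipeline is scored on two maximized objectives: R-squared on the test
split, and the difference score DS = (1/|train R2 - test R2|)^(1/4), which
penalizes overfitting (a model whose train and test scores agree earns a high
DS). Survival selection is NSGA-II; the Pareto archive accumulates every
non-dominated pipeline discovered over the whole run (hall-of-fame
semantics). All randomness flows from a single integer seed, so a run is
bit-reproducible from its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataSplit, validate_phenotype
from .operators import (
    NON_ADDITIVE_ENCODERS,
    REGRESSOR_GRIDS,
    EncodingMap,
    RegressorSpec,
    SelectorSpec,
    fit_regressor,
)
from .pipeline import EmptyPipelineError, PipelineTree, execute_pipeline

__all__ = [
    "GPConfig",
    "FitnessPair",
    "SENTINEL_FITNESS",
    "difference_score",
    "random_pipeline",
    "evaluate_pipeline",
    "mutate",
    "crossover",
    "nsga2_select",
    "ParetoArchive",
    "EvolutionLog",
    "evolve",
    "holdout_scores",
    "summarize_front",
    "FrontSummary",
]

#: Floor on |train R2 - test R2| in the difference score; caps DS at 100.
_DS_FLOOR = 1e-8


def difference_score(train_r2: float, test_r2: float) -> float:
    """Overfitting-penalizing objective: fourth root of 1/|train R2 - test R2|.

    The biquadratic root compresses the scale; the singularity at equal
    scores is floored so DS lies in (0, 100].
    """
    gap = max(abs(train_r2 - test_r2), _DS_FLOOR)
    return (1.0 / gap) ** 0.25


@dataclass(frozen=True)
class FitnessPair:
    """The two Pareto objectives (both maximized) plus the stored train R2."""

    test_r2: float
    ds: float
    train_r2: float = float("nan")

    @property
    def valid(self) -> bool:
        return np.isfinite(self.test_r2) and np.isfinite(self.ds)

    def objectives(self) -> tuple:
        return (self.test_r2, self.ds)


#: Worst-possible fitness assigned to pipelines that remove every feature.
SENTINEL_FITNESS = FitnessPair(test_r2=float("-inf"), ds=float("-inf"))


@dataclass(frozen=True)
class GPConfig:
    """Run parameters for the evolutionary search."""

    population_size: int = 100
    offspring_size: int = 100
    mutation_rate: float = 0.9
    crossover_rate: float = 0.1
    generations: int = 25
    seed: int = 0
    max_phases: int = 6

    def __post_init__(self):
        if self.mutation_rate + self.crossover_rate > 1.0 + 1e-12:
            raise ValueError("mutation_rate + crossover_rate must be <= 1")
        if self.population_size < 1 or self.offspring_size < 1:
            raise ValueError("population and offspring sizes must be positive")
        if self.generations < 0 or self.max_phases < 0:
            raise ValueError("generations and max_phases must be non-negative")


# ---------------------------------------------------------------------------
# Random construction and variation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _random_selector(rng: np.random.Generator) -> SelectorSpec:
    kind = _choice(rng, ("VT", "SP", "GF"))
    spec = SelectorSpec(kind, _choice(rng, _grid_of(kind)))
    return spec


def _grid_of(kind: str):
    from .operators import GF_GRID, SP_GRID, VT_GRID

    return {"VT": VT_GRID, "SP": SP_GRID, "GF": GF_GRID}[kind]


def random_phase(rng: np.random.Generator):
    """A uniformly random phase: encoder or selector with equal probability."""
    if rng.random() < 0.5:
        return EncodingMap.named(_choice(rng, NON_ADDITIVE_ENCODERS))
    return _random_selector(rng)


def random_regressor(rng: np.random.Generator, kind: str | None = None) -> RegressorSpec:
    if kind is None:
        kind = _choice(rng, ("LR", "DT", "RF"))
    grid = REGRESSOR_GRIDS[kind]
    params = tuple((name, _choice(rng, values)) for name, values in grid.items())
    return RegressorSpec(kind, params)


def random_pipeline(rng: np.random.Generator, max_phases: int = 6) -> PipelineTree:
    """Uniformly random pipeline: root kind, grids, and 0..max_phases phases."""
    n_phases = int(rng.integers(max_phases + 1))
    phases = tuple(random_phase(rng) for _ in range(n_phases))
    return PipelineTree(phases=phases, root=random_regressor(rng))


def _mutate_uniform(tree: PipelineTree, rng: np.random.Generator) -> PipelineTree:
    """Replace a random operator, or re-draw one of its hyperparameters."""
    slots = len(tree.phases) + 1  # phases plus the root
    i = int(rng.integers(slots))
    if i == len(tree.phases):  # root node
        reparam = tree.root.params and rng.random() < 0.5
        if reparam:
            name, old = _choice(rng, tree.root.params)
            grid = REGRESSOR_GRIDS[tree.root.kind][name]
            new = old
            while new == old:
                new = _choice(rng, grid)
            params = tuple((k, new if k == name else v) for k, v in tree.root.params)
            return PipelineTree(tree.phases, RegressorSpec(tree.root.kind, params))
        kinds = [k for k in ("LR", "DT", "RF") if k != tree.root.kind]
        return PipelineTree(tree.phases, random_regressor(rng, _choice(rng, kinds)))
    phase = tree.phases[i]
    if isinstance(phase, SelectorSpec) and rng.random() < 0.5:
        grid = _grid_of(phase.kind)
        new = phase.value
        while new == phase.value:
            new = _choice(rng, grid)
        replacement = SelectorSpec(phase.kind, new)
    else:
        replacement = phase
        while _phase_key(replacement) == _phase_key(phase):
            replacement = random_phase(rng)
    phases = tree.phases[:i] + (replacement,) + tree.phases[i + 1 :]
    return PipelineTree(phases, tree.root)


def _phase_key(phase):
    if isinstance(phase, EncodingMap):
        return ("enc", phase.name, phase.table)
    return ("sel", phase.kind, phase.value)


def mutate(tree: PipelineTree, rng: np.random.Generator, max_phases: int = 6) -> PipelineTree:
    """One of three mutation kinds, each with probability 1/3.

    Uniform mutation swaps an operator or re-draws a hyperparameter (the root
    may be swapped but never deleted); insert adds a random phase at a random
    position (refused — resampled as uniform — at the phase cap); shrink
    removes a random phase (a no-op on a phase-free pipeline).
    """
    kind = int(rng.integers(3))
    if kind == 1 and len(tree.phases) >= max_phases:
        kind = 0
    if kind == 0:
        return _mutate_uniform(tree, rng)
    if kind == 1:
        pos = int(rng.integers(len(tree.phases) + 1))
        phases = tree.phases[:pos] + (random_phase(rng),) + tree.phases[pos:]
        return PipelineTree(phases, tree.root)
    if not tree.phases:
        return tree
    pos = int(rng.integers(len(tree.phases)))
    return PipelineTree(tree.phases[:pos] + tree.phases[pos + 1 :], tree.root)


def crossover(a: PipelineTree, b: PipelineTree, rng: np.random.Generator,
              max_phases: int = 6) -> PipelineTree | None:
    """One-point crossover at a shared phase class; first offspring only.

    Two pipelines are eligible when both carry a phase operator of the same
    class (both have an encoding phase, or both a selection phase). The cut
    lands before a uniformly chosen position of that class in each parent;
    the offspring keeps parent A's root and leading phases and takes parent
    B's tail, trimmed to the phase cap. Ineligible pairs return None.
    """
    shared = []
    if a.has_encoder() and b.has_encoder():
        shared.append(EncodingMap)
    if a.has_selector() and b.has_selector():
        shared.append(SelectorSpec)
    if not shared:
        return None
    cls = _choice(rng, shared)
    pos_a = [i for i, p in enumerate(a.phases) if isinstance(p, cls)]
    pos_b = [i for i, p in enumerate(b.phases) if isinstance(p, cls)]
    i = _choice(rng, pos_a)
    j = _choice(rng, pos_b)
    phases = (a.phases[:i] + b.phases[j:])[:max_phases]
    return PipelineTree(phases, a.root)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_pipeline(tree: PipelineTree, X, y, split: DataSplit, seed: int) -> FitnessPair:
    """Fitness of one pipeline: fit on train, score on train and test.

    Selector phases are fit on the training partition only. Pipelines whose
    selectors remove every locus receive the sentinel worst fitness instead
    of raising, so evolution can discard them through selection pressure.
    """
    codes = np.asarray(getattr(X, "codes", X))
    y = validate_phenotype(y, codes.shape[0], require_variation=True)
    tr, te = split.train_idx, split.test_idx
    try:
        Xtr, Xte, _ = execute_pipeline(tree, codes[tr], codes[te], y_train=y[tr])
    except EmptyPipelineError:
        return SENTINEL_FITNESS
    model = fit_regressor(tree.root, Xtr, y[tr], seed=seed)
    train_r2 = float(model.score(Xtr, y[tr]))
    test_r2 = float(model.score(Xte, y[te]))
    return FitnessPair(test_r2=test_r2, ds=difference_score(train_r2, test_r2), train_r2=train_r2)


# ---------------------------------------------------------------------------
# NSGA-II survival selection
# ---------------------------------------------------------------------------

def _dominates(f: FitnessPair, g: FitnessPair) -> bool:
    """True when f is at least as good in both objectives and better in one."""
    return (
        f.test_r2 >= g.test_r2
        and f.ds >= g.ds
        and (f.test_r2 > g.test_r2 or f.ds > g.ds)
    )


def fast_nondominated_sort(fitnesses) -> list:
    """Deb's fast non-dominated sort; returns fronts as index lists."""
    n = len(fitnesses)
    dominated_by = [[] for _ in range(n)]
    dom_count = [0] * n
    fronts = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _dominates(fitnesses[p], fitnesses[q]):
                dominated_by[p].append(q)
            elif _dominates(fitnesses[q], fitnesses[p]):
                dom_count[p] += 1
        if dom_count[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt = []
        for p in fronts[i]:
            for q in dominated_by[p]:
                dom_count[q] -= 1
                if dom_count[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(sorted(nxt))
    return [sorted(f) for f in fronts[:-1]]


def crowding_distance(fitnesses, front) -> dict:
    """Crowding distance of each index in ``front`` (boundaries get +inf)."""
    dist = {i: 0.0 for i in front}
    if len(front) <= 2:
        return {i: float("inf") for i in front}
    for obj in (0, 1):
        vals = {i: fitnesses[i].objectives()[obj] for i in front}
        order = sorted(front, key=lambda i: (vals[i], i))
        dist[order[0]] = dist[order[-1]] = float("inf")
        span = vals[order[-1]] - vals[order[0]]
        if not np.isfinite(span) or span == 0:
            continue
        for a, mid, b in zip(order, order[1:], order[2:]):
            if np.isfinite(dist[mid]):
                dist[mid] += (vals[b] - vals[a]) / span
    return dist


def nsga2_select(candidates, k: int) -> list:
    """NSGA-II survival: fill by front rank, break the last front by crowding.

    ``candidates`` is a list of (tree, FitnessPair). Deterministic given the
    input order: fronts are index-sorted and crowding ties break toward the
    earlier candidate.
    """
    if k > len(candidates):
        raise ValueError(f"cannot select {k} from {len(candidates)} candidates")
    fitnesses = [f for _, f in candidates]
    selected = []
    for front in fast_nondominated_sort(fitnesses):
        if len(selected) + len(front) <= k:
            selected.extend(front)
            if len(selected) == k:
                break
        else:
            cd = crowding_distance(fitnesses, front)
            order = sorted(front, key=lambda i: (-cd[i], i))
            selected.extend(order[: k - len(selected)])
            break
    return [candidates[i][0] for i in selected]


# ---------------------------------------------------------------------------
# Pareto archive
# ---------------------------------------------------------------------------

class ParetoArchive:
    """Cumulative non-dominated set of evaluated pipelines.

    Members are (tree, fitness) pairs; structurally identical pipelines are
    deduplicated and dominated members are evicted on every update.
    """

    def __init__(self):
        self.members: list = []  # list of (PipelineTree, FitnessPair)

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def update(self, evaluated) -> "ParetoArchive":
        pool = list(self.members)
        seen = {t.key() for t, _ in pool}
        for tree, fit in evaluated:
            if not fit.valid:
                continue
            k = tree.key()
            if k in seen:
                continue
            seen.add(k)
            pool.append((tree, fit))
        keep = []
        for i, (_, fi) in enumerate(pool):
            if not any(_dominates(fj, fi) for j, (_, fj) in enumerate(pool) if j != i):
                keep.append(pool[i])
        self.members = keep
        return self

    def trees(self) -> list:
        return [t for t, _ in self.members]

    def best_test_r2(self) -> float:
        return max((f.test_r2 for _, f in self.members), default=float("-inf"))


@dataclass
class GenerationRecord:
    generation: int
    mean_test_r2: float
    max_test_r2: float
    mean_ds: float
    archive_size: int
    best_archive_test_r2: float


@dataclass
class EvolutionLog:
    """Per-generation progress records plus the last-improvement generation."""

    records: list = field(default_factory=list)
    last_improvement: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records])


# ---------------------------------------------------------------------------
# The evolutionary loop
# ---------------------------------------------------------------------------

def evolve(X, y, split: DataSplit, config: GPConfig):
    """Run the full GP loop; returns ``(ParetoArchive, EvolutionLog)``.

    Each generation draws ``offspring_size`` offspring from the current
    population — mutation with probability ``mutation_rate``, else one-point
    crossover with probability ``crossover_rate`` (falling back to a clone
    when the chosen parents are ineligible), else a clone — evaluates them,
    folds them into the archive, and selects the next population from parents
    plus offspring by NSGA-II. Fitness pressure, not parent choice, drives
    which pipelines contribute phases to later generations.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict = {}

    def fitness(tree: PipelineTree) -> FitnessPair:
        k = tree.key()
        if k not in cache:
            cache[k] = evaluate_pipeline(tree, X, y, split, seed=config.seed)
        return cache[k]

    archive = ParetoArchive()
    log = EvolutionLog()

    population = [random_pipeline(rng, config.max_phases) for _ in range(config.population_size)]
    evaluated = [(t, fitness(t)) for t in population]
    archive.update(evaluated)
    _record(log, 0, evaluated, archive)
    prev_keys = {t.key() for t, _ in archive}

    for gen in range(1, config.generations + 1):
        offspring = []
        while len(offspring) < config.offspring_size:
            u = rng.random()
            if u < config.mutation_rate:
                parent = _choice(rng, population)
                child = mutate(parent, rng, config.max_phases)
            elif u < config.mutation_rate + config.crossover_rate:
                pa = _choice(rng, population)
                pb = _choice(rng, population)
                child = crossover(pa, pb, rng, config.max_phases)
                if child is None:
                    child = pa
            else:
                child = _choice(rng, population)
            offspring.append(child)
        evaluated_off = [(t, fitness(t)) for t in offspring]
        archive.update(evaluated_off)
        parents = [(t, fitness(t)) for t in population]
        population = nsga2_select(parents + evaluated_off, config.population_size)
        _record(log, gen, evaluated_off, archive)
        keys = {t.key() for t, _ in archive}
        if keys != prev_keys:
            log.last_improvement = gen
            prev_keys = keys

    return archive, log


def _record(log: EvolutionLog, gen: int, evaluated, archive: ParetoArchive):
    valid = [f for _, f in evaluated if f.valid]
    log.records.append(
        GenerationRecord(
            generation=gen,
            mean_test_r2=float(np.mean([f.test_r2 for f in valid])) if valid else float("nan"),
            max_test_r2=max((f.test_r2 for f in valid), default=float("nan")),
            mean_ds=float(np.mean([f.ds for f in valid])) if valid else float("nan"),
            archive_size=len(archive),
            best_archive_test_r2=archive.best_test_r2(),
        )
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def holdout_scores(archive: ParetoArchive, X, y, split: DataSplit, seed: int) -> list:
    """Holdout R2 of each archive pipeline (refit deterministically on train)."""
    codes = np.asarray(getattr(X, "codes", X))
    y = validate_phenotype(y, codes.shape[0], require_variation=True)
    tr, ho = split.train_idx, split.holdout_idx
    out = []
    for tree, _ in archive:
        Xtr, Xho, _ = execute_pipeline(tree, codes[tr], codes[ho], y_train=y[tr])
        model = fit_regressor(tree.root, Xtr, y[tr], seed=seed)
        out.append(float(model.score(Xho, y[ho])))
    return out


@dataclass
class FrontSummary:
    """Census of a final Pareto front: roots, final encodings, member table."""

    n_pipelines: int
    root_counts: dict
    root_percent: dict
    encoding_counts: dict
    encoding_percent: dict
    members: "object"  # pandas DataFrame


def summarize_front(archive: ParetoArchive) -> FrontSummary:
    """Root-regressor census and final-encoding classification of the front.

    A member is flagged Pareto efficient when no other member has both
    strictly higher test R2 and strictly higher DS.
    """
    import pandas as pd

    if len(archive) == 0:
        raise ValueError("archive is empty; nothing to summarize")
    rows = []
    fits = [f for _, f in archive]
    for i, (tree, fit) in enumerate(archive):
        efficient = not any(
            g.test_r2 > fit.test_r2 and g.ds > fit.ds for j, g in enumerate(fits) if j != i
        )
        rows.append(
            {
                "pipeline": tree.describe(),
                "root": tree.root.kind,
                "n_phases": tree.n_phases,
                "encoding_class": tree.encoding_class(),
                "train_r2": fit.train_r2,
                "test_r2": fit.test_r2,
                "ds": fit.ds,
                "pareto_efficient": efficient,
            }
        )
    members = pd.DataFrame(rows)
    n = len(members)
    root_counts = members["root"].value_counts().to_dict()
    enc_counts = members["encoding_class"].value_counts().to_dict()
    return FrontSummary(
        n_pipelines=n,
        root_counts=root_counts,
        root_percent={k: 100.0 * v / n for k, v in root_counts.items()},
        encoding_counts=enc_counts,
        encoding_percent={k: 100.0 * v / n for k, v in enc_counts.items()},
        members=members,
    )
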