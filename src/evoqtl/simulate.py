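"""Synthetic genotype/phenotype generation and XOR-epistasis injection.

Genotypes are drawn locus-by-locus under Hardy-Weinberg equilibrium at a
configurable minor-allele frequency. Pure two-locus epistasis uses the XOR
penetrance model: penetrance 1 exactly when one of the two loci is
heterozygous, which under HWE at allele frequency 0.5 gives every single-locus
genotype a marginal penetrance of 0.5 — i.e. no marginal (main) effect at
either locus, so the interaction is invisible to per-locus regression.

Interactions are written into an existing dataset by jointly permuting the two
loci's genotype rows so that penetrance-1 combinations occupy the top
phenotype ranks; the multiset of two-locus combinations — hence every genotype
and allele frequency — is preserved bit-exactly. Partial random re-shuffling
then weakens the signal, and a bisection calibrates the shuffle fraction until
a reference random-forest probe detects a chosen test R2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .data import DataSplit, GenotypeMatrix, split_data
from .operators import N_TREES

__all__ = [
    "XOR_PENETRANCE",
    "xor_penetrance",
    "hwe_weights",
    "marginal_penetrance",
    "SimConfig",
    "InteractionPlan",
    "simulate_hwe_genotypes",
    "simulate_additive_phenotype",
    "additive_noise_sd_for_target_r2",
    "inject_xor_pair",
    "inject_xor_pairs",
    "shuffle_fraction",
    "permute_column",
    "detectable_r2",
    "calibrate_to_target_r2",
    "build_interaction_ladder",
    "LadderResult",
    "REFERENCE_RF_PARAMS",
]

# The XOR two-locus penetrance table, indexed [genotype A, genotype B]:
# penetrance 1 iff exactly one locus is heterozygous. This is the unique
# symmetric 0/1 table whose HWE(0.5)-weighted marginal penetrance is 0.5 for
# every single-locus genotype; swap in an alternative table here if needed.
XOR_PENETRANCE = np.array(
    [[0, 1, 0],
     [1, 0, 1],
     [0, 1, 0]], dtype=np.int64
)


def xor_penetrance(g_a: int, g_b: int) -> int:
    """Penetrance of a two-locus genotype combination under the XOR model."""
    if g_a not in (0, 1, 2) or g_b not in (0, 1, 2):
        raise ValueError(f"genotype codes must be in {{0,1,2}}, got ({g_a}, {g_b})")
    return int(XOR_PENETRANCE[g_a, g_b])


def hwe_weights(q: float = 0.5) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def marginal_penetrance(q: float = 0.5) -> np.ndarray:
    """HWE-weighted marginal penetrance for the six single-locus genotypes.

    Returns a (2, 3) array: row 0 conditions on locus A's genotype, row 1 on
    locus B's. Under the XOR table at q = 0.5 every entry is exactly 0.5.
    """
    w = hwe_weights(q)
    by_a = XOR_PENETRANCE @ w          # condition on g_a, average over g_b
    by_b = w @ XOR_PENETRANCE          # condition on g_b, average over g_a
    return np.vstack([by_a, by_b])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the HWE genotype/additive phenotype generator."""

    n_samples: int
    n_loci: int = 18
    maf: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")


def simulate_hwe_genotypes(config: SimConfig) -> GenotypeMatrix:
    """I.i.d. genotypes per locus with HWE probabilities at ``config.maf``."""
    rng = np.random.default_rng(config.seed)
    probs = hwe_weights(config.maf)
    codes = rng.choice(3, size=(config.n_samples, config.n_loci), p=probs)
    return GenotypeMatrix(
        sample_ids=tuple(range(config.n_samples)),
        locus_ids=tuple(f"L{j + 1:02d}" for j in range(config.n_loci)),
        codes=codes.astype(np.int64),
    )


def simulate_additive_phenotype(X, betas, noise_sd: float, seed: int) -> np.ndarray:
    """``y = X @ betas + N(0, noise_sd)``, the pure-main-effect regime."""
    codes = np.asarray(getattr(X, "codes", X), dtype=float)
    betas = np.asarray(betas, dtype=float)
    if len(betas) != codes.shape[1]:
        raise ValueError(f"{len(betas)} betas for {codes.shape[1]} loci")
    rng = np.random.default_rng(seed)
    return codes @ betas + rng.normal(0.0, noise_sd, size=codes.shape[0])


def additive_noise_sd_for_target_r2(betas, maf: float, target_r2: float) -> float:
    """Noise SD making the population R2 of the additive model ``target_r2``.

    Uses the HWE genotype variance 2q(1-q) per locus; loci are independent,
    so explained variance is ``sum(beta_j^2) * 2q(1-q)``.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    explained = float(np.sum(np.asarray(betas, dtype=float) ** 2)) * 2 * maf * (1 - maf)
    return float(np.sqrt(explained * (1 - target_r2) / target_r2))


@dataclass(frozen=True)
class InteractionPlan:
    """Disjoint locus pairs to convert into XOR interactions."""

    pairs: tuple
    target_r2: float = 0.10
    mode: str = "replace_noise"
    seed: int = 0

    def __post_init__(self):
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        flat = [i for p in pairs for i in p]
        if len(set(flat)) != len(flat):
            raise ValueError("interaction pairs must be disjoint: no locus used twice")
        if self.mode not in ("replace_noise", "replace_main_effects"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "pairs", pairs)


def _codes_of(X) -> np.ndarray:
    return np.asarray(getattr(X, "codes", X))


def _rewrap(X, codes: np.ndarray):
    return X.with_codes(codes) if isinstance(X, GenotypeMatrix) else codes


def inject_xor_pair(X, y, pair, seed: int):
    """Write one maximal-strength XOR interaction between two loci.

    The rows of the pair's two columns are jointly re-assigned so that
    penetrance-1 two-locus combinations sit at the highest phenotype ranks
    (as many as exist) and penetrance-0 combinations fill the rest; ties at
    the median boundary break by sample index (stable sort). The combination
    multiset is preserved exactly, so genotype and allele frequencies are
    untouched while the genotype-phenotype relationship becomes pure
    epistasis.
    """
    a, b = int(pair[0]), int(pair[1])
    codes = _codes_of(X).copy()
    n, m = codes.shape
    if a == b or not (0 <= a < m and 0 <= b < m):
        raise ValueError(f"invalid locus pair ({a}, {b}) for {m} loci")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    combos = codes[:, (a, b)]
    pen = XOR_PENETRANCE[combos[:, 0], combos[:, 1]]
    pen1 = combos[pen == 1]
    pen0 = combos[pen == 0]
    rng.shuffle(pen1)
    rng.shuffle(pen0)
    order = np.argsort(y, kind="stable")  # ascending phenotype rank
    k = len(pen1)
    top, rest = order[n - k :], order[: n - k]
    codes[top[:, None], (a, b)] = pen1
    if len(rest):
        codes[rest[:, None], (a, b)] = pen0
    return _rewrap(X, codes)


def inject_xor_pairs(X, y, pairs, seed: int):
    """Inject several XOR pairs; pairs must be pairwise disjoint."""
    plan = InteractionPlan(pairs=tuple(pairs), seed=seed)  # validates disjointness
    out = X
    for i, pair in enumerate(plan.pairs):
        out = inject_xor_pair(out, y, pair, seed=_subseed(seed, i))
    return out


def _subseed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(i)]).generate_state(1)[0] % (2**31))


def shuffle_fraction(X, pair, fraction: float, seed: int):
    """Re-permute a pair's two-locus combinations among a random row subset.

    ``floor(fraction * n)`` rows are chosen; their (A, B) combination tuples
    are permuted jointly, which weakens the genotype-phenotype association
    while preserving the combination multiset exactly.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    a, b = int(pair[0]), int(pair[1])
    codes = _codes_of(X).copy()
    n = codes.shape[0]
    k = int(np.floor(fraction * n))
    if k >= 2:
        rng = np.random.default_rng(seed)
        rows = rng.choice(n, size=k, replace=False)
        perm = rng.permutation(rows)
        codes[rows[:, None], (a, b)] = codes[perm[:, None], (a, b)]
    return _rewrap(X, codes)


def permute_column(X, locus: int, seed: int):
    """Independent uniform permutation of one column's rows.

    Destroys that locus's association with the phenotype in expectation while
    preserving its genotype counts exactly.
    """
    codes = _codes_of(X).copy()
    if not 0 <= locus < codes.shape[1]:
        raise ValueError(f"locus {locus} out of range")
    rng = np.random.default_rng(seed)
    codes[:, locus] = codes[rng.permutation(codes.shape[0]), locus]
    return _rewrap(X, codes)


#: Reference probe regressor used to measure "detectable" epistatic R2.
REFERENCE_RF_PARAMS = dict(
    bootstrap=True, max_features=0.25, min_samples_leaf=5, min_samples_split=10
)


def detectable_r2(X, y, seed: int, regressor: str = "rf", split: DataSplit | None = None) -> float:
    """Test-split R2 of a fixed probe model fit on the train split.

    ``regressor="rf"`` uses the reference random forest (interaction-capable);
    ``"lr"`` uses plain multiple linear regression (main effects only).
    """
    codes = _codes_of(X).astype(float)
    y = np.asarray(y, dtype=float)
    if split is None:
        split = split_data(codes.shape[0], seed)
    tr, te = split.train_idx, split.test_idx
    if regressor == "rf":
        model = RandomForestRegressor(n_estimators=N_TREES, random_state=seed, **REFERENCE_RF_PARAMS)
    elif regressor == "lr":
        from sklearn.linear_model import LinearRegression

        model = LinearRegression()
    else:
        raise ValueError(f"unknown probe regressor {regressor!r}")
    model.fit(codes[tr], y[tr])
    return float(model.score(codes[te], y[te]))


def calibrate_to_target_r2(X, y, plan: InteractionPlan, evaluator=None,
                           max_iter: int = 20, tol: float = 0.01):
    """Bisect a common shuffle fraction until the probe R2 hits the target.

    ``X`` must already carry the plan's pairs injected at full strength.
    Every candidate dataset re-shuffles each pair from that clean state with
    the same fraction (seeded per iteration). Errors if the target exceeds
    the unshuffled ceiling. Returns ``(dataset, achieved_r2)``.
    """
    if evaluator is None:
        evaluator = lambda Xc, yc: detectable_r2(Xc, yc, seed=plan.seed, regressor="rf")

    def candidate(fraction: float, it: int):
        out = X
        for i, pair in enumerate(plan.pairs):
            out = shuffle_fraction(out, pair, fraction, seed=_subseed(plan.seed, 1000 * it + i))
        return out

    ceiling = evaluator(X, y)
    if plan.target_r2 > ceiling + tol:
        raise ValueError(
            f"target R2 {plan.target_r2:.3f} exceeds the unshuffled ceiling {ceiling:.3f}"
        )
    if abs(ceiling - plan.target_r2) <= tol:
        return X, ceiling
    lo, hi = 0.0, 1.0  # R2 decreases as the shuffled fraction grows
    best, best_r2 = X, ceiling
    for it in range(max_iter):
        mid = (lo + hi) / 2
        Xc = candidate(mid, it)
        r2 = evaluator(Xc, y)
        if abs(r2 - plan.target_r2) < abs(best_r2 - plan.target_r2):
            best, best_r2 = Xc, r2
        if abs(r2 - plan.target_r2) <= tol:
            return Xc, r2
        if r2 > plan.target_r2:
            lo = mid
        else:
            hi = mid
    return best, best_r2


@dataclass
class LadderResult:
    """Datasets with 0..k injected interactions, plus the pairs used."""

    datasets: list
    pairs: tuple
    mode: str


def build_interaction_ladder(X, y, k: int, mode: str, seed: int) -> LadderResult:
    """Datasets with an increasing number of XOR interactions (0..k).

    ``replace_noise`` starts from a copy with every column independently
    permuted (all main effects destroyed) and injects one further XOR pair
    per rung. ``replace_main_effects`` starts from the intact data; each rung
    permutes the next pair's two columns (breaking their main effects) and
    then injects the XOR pair on them. Pairs are random, disjoint throughout.
    """
    codes = _codes_of(X)
    m = codes.shape[1]
    if 2 * k > m:
        raise ValueError(f"{k} pairs need {2 * k} loci but only {m} available")
    if mode not in ("replace_noise", "replace_main_effects"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    pairs = tuple((int(order[2 * i]), int(order[2 * i + 1])) for i in range(k))

    if mode == "replace_noise":
        base = X
        for j in range(m):
            base = permute_column(base, j, seed=_subseed(seed, j))
    else:
        base = X
    datasets = [base]
    current = base
    for i, pair in enumerate(pairs):
        if mode == "replace_main_effects":
            current = permute_column(current, pair[0], seed=_subseed(seed, 10_000 + 2 * i))
            current = permute_column(current, pair[1], seed=_subseed(seed, 10_000 + 2 * i + 1))
        current = inject_xor_pair(current, y, pair, seed=_subseed(seed, 20_000 + i))
        datasets.append(current)
    return LadderResult(datasets=datasets, pairs=pairs, mode=mode)
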