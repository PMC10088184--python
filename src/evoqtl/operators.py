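"""The three pipeline operator classes: inheritance-model encoders, genetic
feature selectors, and regression roots, with their hyperparameter grids.

Encoders recode every locus's genotypes through a total map on {0, 1, 2},
expressing inheritance models beyond the additive default — e.g. the dominant
map collapses Aa with aa, the heterosis map gives the two homozygotes equal
value. Selectors drop loci by variance, univariate association, or genotype
frequency. Roots are ordinary least squares or tree-based regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ENCODER_TABLES",
    "NON_ADDITIVE_ENCODERS",
    "EncodingMap",
    "compose_encodings",
    "SelectorSpec",
    "VT_GRID",
    "SP_GRID",
    "GF_GRID",
    "vt_mask",
    "f_regression_scores",
    "sp_mask",
    "gf_mask",
    "RegressorSpec",
    "REGRESSOR_GRIDS",
    "N_TREES",
    "fit_regressor",
]

# Canonical encoder tables, one place so an alternative convention can be
# swapped in. Keys map input code {0,1,2} -> output code by position.
# dominant/recessive/heterosis collapse the three genotype values to two
# ("2-level" inheritance models); overdominance/underdominance keep three.
# Heterosis gives both homozygotes the same value and the heterozygote another.
ENCODER_TABLES: dict[str, tuple[int, int, int]] = {
    "additive": (0, 1, 2),
    "dominant": (0, 2, 2),
    "recessive": (0, 0, 2),
    "heterosis": (0, 2, 0),
    "overdominance": (0, 2, 1),
    "underdominance": (1, 0, 2),
}

#: The five encoders a pipeline may select (additive is the do-nothing default).
NON_ADDITIVE_ENCODERS = ("dominant", "recessive", "heterosis", "overdominance", "underdominance")


@dataclass(frozen=True)
class EncodingMap:
    """A total genotype recoding {0,1,2} -> {0,1,2}."""

    name: str
    table: tuple

    def __post_init__(self):
        table = tuple(int(v) for v in self.table)
        if len(table) != 3 or any(v not in (0, 1, 2) for v in table):
            raise ValueError(f"encoding table must map {{0,1,2}} into {{0,1,2}}, got {table}")
        object.__setattr__(self, "table", table)

    @classmethod
    def named(cls, name: str) -> "EncodingMap":
        try:
            return cls(name, ENCODER_TABLES[name])
        except KeyError:
            raise ValueError(f"unknown encoder {name!r}") from None

    @property
    def n_levels(self) -> int:
        """Number of distinct output genotype values."""
        return len(set(self.table))

    def apply(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes)
        if codes.size and (codes.min() < 0 or codes.max() > 2):
            raise ValueError("genotype code outside {0,1,2}")
        return np.asarray(self.table, dtype=codes.dtype)[codes]


def apply_encoding(X, mapping: EncodingMap):
    """Element-wise recode of every cell; identifiers unchanged.

    Accepts a :class:`~evoqtl.data.GenotypeMatrix` (returned re-wrapped) or a
    plain array.
    """
    codes = getattr(X, "codes", None)
    if codes is None:
        return mapping.apply(np.asarray(X))
    return X.with_codes(mapping.apply(codes))


def compose_encodings(maps) -> EncodingMap:
    """Left-to-right functional composition of encoder maps over {0,1,2}.

    The result is itself a valid map, possibly matching no single named
    encoder — sequential encoding phases can reach such states.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one encoding map to compose")
    table = (0, 1, 2)
    for m in maps:
        table = tuple(m.table[v] for v in table)
    name = "+".join(m.name for m in maps) if len(maps) > 1 else maps[0].name
    return EncodingMap(name, table)


# ---------------------------------------------------------------------------
# Feature selectors
# ---------------------------------------------------------------------------

VT_GRID = tuple(round(0.05 * i, 2) for i in range(8))       # 0.00 .. 0.35
GF_GRID = VT_GRID
SP_GRID = tuple(range(5, 100, 5))                           # 5 .. 95 percent

_SELECTOR_GRIDS = {"VT": VT_GRID, "SP": SP_GRID, "GF": GF_GRID}


@dataclass(frozen=True)
class SelectorSpec:
    """A feature-selection phase: kind in {VT, SP, GF} plus its grid value."""

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in _SELECTOR_GRIDS:
            raise ValueError(f"unknown selector kind {self.kind!r}")
        grid = _SELECTOR_GRIDS[self.kind]
        if self.value not in grid:
            raise ValueError(f"{self.kind} value {self.value} not in grid {grid}")

    @property
    def grid(self):
        return _SELECTOR_GRIDS[self.kind]


def vt_mask(X, threshold: float) -> np.ndarray:
    """Keep loci whose population variance is strictly above ``threshold``.

    Strict inequality means threshold 0 already removes constant columns.
    """
    X = np.asarray(getattr(X, "codes", X), dtype=float)
    return X.var(axis=0) > threshold


def f_regression_scores(X, y) -> np.ndarray:
    """Univariate F statistic of each locus against the phenotype.

    ``F_j = r_j^2 / (1 - r_j^2) * (n - 2)`` with ``r_j`` the Pearson
    correlation of column j with y. Constant columns score 0; a perfectly
    correlated column scores +inf (ranked above every finite score).
    """
    X = np.asarray(getattr(X, "codes", X), dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    scores = np.zeros(X.shape[1])
    ok = sx > 0
    if sy > 0 and ok.any():
        r = np.clip((xc[:, ok] * yc[:, None]).sum(axis=0) / (sx[ok] * sy), -1.0, 1.0)
        with np.errstate(divide="ignore"):
            f = r**2 / (1.0 - r**2) * (n - 2)
        f[np.abs(r) > 1 - 1e-12] = np.inf  # perfect correlation outranks all
        scores[ok] = f
    return scores


def sp_mask(X, y, percentile: int) -> np.ndarray:
    """Keep the loci whose F scores fall in the top ``percentile`` percent.

    Kept count is ``max(1, round(percentile/100 * m))`` (half rounds up);
    score ties break toward the lower column index.
    """
    scores = f_regression_scores(X, y)
    m = len(scores)
    k = max(1, int(np.floor(percentile / 100.0 * m + 0.5)))
    order = np.argsort(-scores, kind="stable")  # stable: ties keep index order
    keep = np.zeros(m, dtype=bool)
    keep[order[:k]] = True
    return keep


def gf_mask(X, threshold: float) -> np.ndarray:
    """Remove loci where any genotype frequency falls below ``threshold``.

    Frequencies are computed over the genotype values actually present in the
    column, so a 2-level-encoded locus with a 50/50 split of two values is not
    penalized for the absent third class.
    """
    X = np.asarray(getattr(X, "codes", X))
    n, m = X.shape
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        _, counts = np.unique(X[:, j], return_counts=True)
        keep[j] = counts.min() / n >= threshold
    return keep


# ---------------------------------------------------------------------------
# Regression roots
# ---------------------------------------------------------------------------

#: Random-forest tree count; fixed, not an evolved hyperparameter.
N_TREES = 100

REGRESSOR_GRIDS: dict[str, dict[str, tuple]] = {
    "LR": {},
    "DT": {
        "max_depth": tuple(range(1, 11)),
        "min_samples_leaf": tuple(range(1, 21)),
        "min_samples_split": tuple(range(2, 21)),
    },
    "RF": {
        "bootstrap": (True, False),
        "max_features": tuple(round(0.05 * i, 2) for i in range(1, 21)),
        "min_samples_leaf": tuple(range(1, 21)),
        "min_samples_split": tuple(range(2, 21)),
    },
}


@dataclass(frozen=True)
class RegressorSpec:
    """A root regressor: LR (no hyperparameters), DT or RF with grid values."""

    kind: str
    params: tuple = ()

    def __post_init__(self):
        if self.kind not in REGRESSOR_GRIDS:
            raise ValueError(f"unknown regressor kind {self.kind!r}")
        params = tuple((str(k), v) for k, v in self.params)
        grid = REGRESSOR_GRIDS[self.kind]
        if set(k for k, _ in params) != set(grid):
            raise ValueError(f"{self.kind} requires hyperparameters {sorted(grid)}")
        for k, v in params:
            if v not in grid[k]:
                raise ValueError(f"{self.kind} {k}={v} not in grid")
        object.__setattr__(self, "params", params)

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def fit_regressor(spec: RegressorSpec, X, y, seed: int, n_trees: int = N_TREES):
    """Fit the root regressor; all tree randomness is driven by ``seed``."""
    X = np.asarray(getattr(X, "codes", X), dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("empty pipeline: no features left to fit the root regressor")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; cannot fit models")
    p = spec.param_dict
    if spec.kind == "LR":
        model = LinearRegression()
    elif spec.kind == "DT":
        model = DecisionTreeRegressor(random_state=seed, **p)
    else:
        model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, **p)
    model.fit(X, y)
    return model
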