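"""Genotype/phenotype dataset container, file I/O, data splitting and the
additive multiple-regression baseline.

A dataset is ``n`` samples by ``m`` biallelic loci, each genotype coded as the
count of one allele (AA = 0, Aa = 1, aa = 2), plus one continuous phenotype
column (typically residuals left after upstream covariate correction). Samples
are rows, loci are columns; loading rejects missing or out-of-range cells
outright — imputation is upstream of this tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

__all__ = [
    "GenotypeMatrix",
    "DataSplit",
    "read_dataset",
    "write_dataset",
    "validate_phenotype",
    "split_data",
    "baseline_multiple_lr_r2",
]

VALID_CODES = (0, 1, 2)


@dataclass(frozen=True, eq=False)
class GenotypeMatrix:
    """An ``n_samples x n_loci`` matrix of genotype codes in {0, 1, 2}.

    ``sample_ids`` and ``locus_ids`` are unique identifiers aligned to rows and
    columns respectively; ``codes`` is a small-integer numpy array.
    """

    sample_ids: tuple
    locus_ids: tuple
    codes: np.ndarray

    def __post_init__(self):
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if not np.issubdtype(codes.dtype, np.integer):
            if not np.all(codes == codes.astype(np.int64)):
                raise ValueError("genotype codes must be integers")
            codes = codes.astype(np.int64)
        if codes.size and not np.isin(codes, VALID_CODES).all():
            bad = np.argwhere(~np.isin(codes, VALID_CODES))[0]
            raise ValueError(
                f"genotype code {codes[bad[0], bad[1]]} at sample "
                f"{self.sample_ids[bad[0]]!r}, locus {self.locus_ids[bad[1]]!r} "
                f"is outside {{0, 1, 2}}"
            )
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "locus_ids", tuple(self.locus_ids))
        if codes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample identifiers are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus identifiers are not unique")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def with_codes(self, codes: np.ndarray) -> "GenotypeMatrix":
        """Same identifiers, new code matrix."""
        return GenotypeMatrix(self.sample_ids, self.locus_ids, codes)

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.codes, other.codes)
        )


@dataclass(frozen=True)
class DataSplit:
    """Disjoint holdout (~20%) / train (~40%) / test (~40%) index sets.

    The holdout split is reserved for scoring final Pareto-front pipelines; all
    evolution happens on the train/test halves of the remainder.
    """

    holdout_idx: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        for name in ("holdout_idx", "train_idx", "test_idx"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        all_idx = np.concatenate([self.holdout_idx, self.train_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")

    @property
    def n_samples(self) -> int:
        return len(self.holdout_idx) + len(self.train_idx) + len(self.test_idx)

    def partition(self, name: str) -> np.ndarray:
        try:
            return {"holdout": self.holdout_idx, "train": self.train_idx, "test": self.test_idx}[name]
        except KeyError:
            raise ValueError(f"unknown partition {name!r}; expected train/test/holdout") from None


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_dataset(path, phenotype_column: str):
    """Read a genotype/phenotype table; return ``(GenotypeMatrix, phenotype)``.

    The header row holds locus identifiers plus the phenotype column; every
    other cell must be a genotype code in {0, 1, 2}. Column order is preserved
    as locus order. Comma vs. tab dialect is picked from the file extension
    (.tsv/.tab/.txt are tab-separated).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_separator_for(path))
    if phenotype_column not in df.columns:
        raise ValueError(f"phenotype column {phenotype_column!r} not found in {path.name}")
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValueError(f"missing value at row {row}, column {col!r}")
    y = df[phenotype_column].to_numpy()
    if not np.issubdtype(y.dtype, np.number):
        raise ValueError(f"phenotype column {phenotype_column!r} is not numeric")
    geno = df.drop(columns=[phenotype_column])
    for col in geno.columns:
        vals = geno[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(vals == np.floor(vals)):
            raise ValueError(f"non-integer genotype in column {col!r}")
        bad = ~np.isin(vals.astype(np.int64), VALID_CODES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"genotype code {vals[row]} at row {row}, column {col!r} is outside {{0, 1, 2}}"
            )
    X = GenotypeMatrix(
        sample_ids=tuple(range(len(df))),
        locus_ids=tuple(str(c) for c in geno.columns),
        codes=geno.to_numpy(dtype=np.int64),
    )
    return X, y.astype(float)


def write_dataset(path, X: GenotypeMatrix, y, phenotype_column: str = "phenotype"):
    """Write a dataset in the same dialect :func:`read_dataset` accepts."""
    path = Path(path)
    y = validate_phenotype(y, X.n_samples)
    df = pd.DataFrame(X.codes, columns=list(X.locus_ids))
    df[phenotype_column] = y
    df.to_csv(path, sep=_separator_for(path), index=False)
    return path


def validate_phenotype(y, n_samples: int, require_variation: bool = False) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != n_samples:
        raise ValueError(f"phenotype length {len(y)} != {n_samples} samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if require_variation and np.ptp(y) == 0:
        raise ValueError("phenotype is constant; cannot fit models")
    return y


def split_data(n_samples: int, seed: int) -> DataSplit:
    """Random holdout/train/test split driven solely by ``seed``.

    Holdout gets ``floor(0.2 n)`` samples; the remainder is halved into train
    and test with the odd sample, if any, going to test.
    """
    if n_samples < 10:
        raise ValueError(f"need at least 10 samples to split, got {n_samples}")
    perm = np.random.default_rng(seed).permutation(n_samples)
    n_holdout = int(np.floor(0.2 * n_samples))
    remaining = n_samples - n_holdout
    n_train = remaining // 2
    return DataSplit(
        holdout_idx=perm[:n_holdout],
        train_idx=perm[n_holdout : n_holdout + n_train],
        test_idx=perm[n_holdout + n_train :],
        seed=seed,
    )


def _as_codes(X) -> np.ndarray:
    return np.asarray(getattr(X, "codes", X), dtype=float)


def baseline_multiple_lr_r2(X, y, split: DataSplit | None = None, partition: str = "test") -> float:
    """R-squared of ordinary multiple linear regression of ``y`` on all loci.

    Under additive coding this is the phenotypic variance explained by main
    effects. With ``split=None`` the model is fit and scored on the full data;
    otherwise it is fit on the train partition and scored on ``partition``
    (which may give a negative value out of sample). Singular designs are
    handled by least squares without error.
    """
    codes = _as_codes(X)
    y = validate_phenotype(y, codes.shape[0], require_variation=True)
    model = LinearRegression()
    if split is None:
        model.fit(codes, y)
        return float(model.score(codes, y))
    model.fit(codes[split.train_idx], y[split.train_idx])
    idx = split.partition(partition)
    return float(model.score(codes[idx], y[idx]))
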