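"""Shared data model: count matrices, design matrices and library sizes.

A count matrix is features-by-samples (``G x n``) of non-negative integer
read counts.  Designs are ``n x p`` real matrices with full column rank and
at least one residual degree of freedom.  Library sizes carry raw totals,
normalization factors and the effective sizes that enter GLM offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "DesignMatrix",
    "LibrarySizeSet",
    "make_group_design",
    "filter_low_counts",
]


@dataclass
class CountMatrix:
    """Features-by-samples table of non-negative integer read counts.

    Counts are validated as integral on construction but stored as floats so
    that downstream weighted working quantities need no conversion.
    """

    values: np.ndarray
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("counts must be a 2-D features-by-samples matrix")
        G, n = values.shape
        # G == 0 can legitimately arise from filtering; it warns upstream.
        if n < 2:
            raise ValueError("need at least two samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("counts must be finite")
        if np.any(values < 0):
            g, i = np.argwhere(values < 0)[0]
            raise ValueError(f"negative count at feature row {g}, sample column {i}")
        if np.any(values != np.round(values)):
            g, i = np.argwhere(values != np.round(values))[0]
            raise ValueError(f"non-integer count at feature row {g}, sample column {i}")
        self.values = values
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{g}" for g in range(G)]
        else:
            self.feature_ids = [str(x) for x in self.feature_ids]
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        else:
            self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.feature_ids) != G:
            raise ValueError("feature_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.feature_ids)) != G:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Raw per-sample total counts."""
        return self.values.sum(axis=0)

    def subset_features(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            self.values[index],
            [self.feature_ids[int(g)] for g in index],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.astype(np.int64), index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.to_numpy(), list(frame.index.astype(str)), list(frame.columns.astype(str)))


@dataclass
class DesignMatrix:
    """``n x p`` real design matrix with the tested coefficient subset."""

    values: np.ndarray
    column_names: list[str] = field(default=None)  # type: ignore[assignment]
    coef_of_interest: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("design must be 2-D (samples x coefficients)")
        n, p = values.shape
        if not np.all(np.isfinite(values)):
            raise ValueError("design entries must be finite")
        if p >= n:
            raise ValueError(f"design leaves no residual degrees of freedom (p={p}, n={n})")
        if np.linalg.matrix_rank(values) < p:
            raise ValueError("design matrix is column-rank deficient")
        self.values = values
        if self.column_names is None:
            self.column_names = [f"coef_{j}" for j in range(p)]
        if len(self.column_names) != p:
            raise ValueError("column_names length does not match design width")
        self.coef_of_interest = [int(j) for j in self.coef_of_interest]
        if any(j < 0 or j >= p for j in self.coef_of_interest):
            raise ValueError("coef_of_interest indices out of range")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.values.shape[1]

    def reduced(self) -> "DesignMatrix":
        """Null design: all columns except those of interest."""
        keep = [j for j in range(self.n_coefficients) if j not in self.coef_of_interest]
        if not keep:
            raise ValueError("reduced design would be empty")
        return DesignMatrix(self.values[:, keep], [self.column_names[j] for j in keep], [])


@dataclass
class LibrarySizeSet:
    """Raw library sizes, normalization factors and effective sizes.

    Effective sizes are elementwise products ``raw * factor``; factors are
    geometric-mean centred so their product is one.
    """

    raw_sizes: np.ndarray
    norm_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_sizes, dtype=float)
        if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
            raise ValueError("raw library sizes must be positive and finite")
        self.raw_sizes = raw
        if self.norm_factors is None:
            self.norm_factors = np.ones_like(raw)
        else:
            f = np.asarray(self.norm_factors, dtype=float)
            if np.any(f <= 0) or not np.all(np.isfinite(f)):
                raise ValueError("normalization factors must be positive and finite")
            if f.shape != raw.shape:
                raise ValueError("factors and raw sizes must align")
            self.norm_factors = f

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.raw_sizes * self.norm_factors

    @property
    def offsets(self) -> np.ndarray:
        """Natural-log effective sizes, the GLM offset per sample."""
        return np.log(self.effective_sizes)

    @classmethod
    def from_counts(cls, counts: CountMatrix) -> "LibrarySizeSet":
        return cls(counts.library_sizes)


def make_group_design(groups) -> DesignMatrix:
    """Build an intercept + treatment-contrast design from a group label vector.

    The alphabetically first group is the reference level; every non-intercept
    column is a coefficient of interest (a log-fold-change versus reference).
    """
    labels = [str(g) for g in groups]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two samples")
    levels = sorted(set(labels))
    p = len(levels)
    if p >= n and p > 1:
        raise ValueError(f"one sample per group leaves no residual degrees of freedom (groups={p}, samples={n})")
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = [1.0 if lab == lev else 0.0 for lab in labels]
    names = ["intercept"] + [f"{lev}_vs_{levels[0]}" for lev in levels[1:]]
    return DesignMatrix(X, names, list(range(1, p)))


def filter_low_counts(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    libs: LibrarySizeSet | None = None,
) -> tuple[CountMatrix, np.ndarray]:
    """Keep features with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    Returns the filtered matrix and the integer index of retained features
    (original order preserved).  An empty result warns rather than raising.
    """
    if min_samples > counts.n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    if libs is None:
        libs = LibrarySizeSet.from_counts(counts)
    cpm = counts.values / libs.effective_sizes[None, :] * 1e6
    keep = np.flatnonzero((cpm >= min_cpm).sum(axis=1) >= min_samples)
    if keep.size == 0:
        warnings.warn("low-count filter removed every feature", stacklevel=2)
    return counts.subset_features(keep), keep
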