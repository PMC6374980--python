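"""Tract phenotype handling: outlier exclusion and latent-factor extraction.

The 27 tract-averaged values per modality (12 bilateral tracts x 2
hemispheres + 3 unilateral tracts) are reduced to latent scores by principal
component analysis of the standardized columns: a global factor over all 27
columns and one factor per tract category.  The first unrotated component is
used, with its sign fixed so that the sum of loadings is positive (a higher
score means globally higher FA or MD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tractprs import tracts as _tracts


@dataclass
class TractMatrix:
    """Wide subjects x 27 matrix of tract-averaged values for one modality."""

    values: pd.DataFrame  # columns: MultiIndex (tract, hemisphere)
    measure: str  # "FA" or "MD"

    def __post_init__(self) -> None:
        if self.measure not in _tracts.MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        expected = _tracts.tract_columns()
        got = [tuple(c) for c in self.values.columns]
        if sorted(got) != sorted(expected):
            raise ValueError(
                f"expected the 27 catalogue columns, got {len(got)} columns"
            )

    def category_columns(self, category: str) -> pd.DataFrame:
        cols = _tracts.tract_columns(category)
        return self.values[cols]


@dataclass
class LatentScores:
    """First-unrotated-component scores and their % variance explained."""

    scores: pd.Series  # index: subject ids; sample mean 0
    pct_variance: float
    loadings: pd.Series | None = None


def exclude_outliers(
    tracts: TractMatrix, k: float = 3.0
) -> tuple[TractMatrix, list]:
    """Drop subjects with any tract value beyond k SDs from the column mean.

    Means and SDs are computed on the unfiltered sample and the rule is
    applied once (not iterated); a value strictly outside mean +/- k*SD in
    any of the 27 columns excludes the subject from this modality.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    vals = tracts.values.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        # a zero-SD column with non-identical values signals corrupt input
        for j in np.flatnonzero(zero_var):
            if not np.allclose(vals[:, j], mu[j]):
                raise ValueError(
                    f"column {tracts.values.columns[j]} has zero variance "
                    "but non-identical values"
                )
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.abs(vals - mu)
        outlying = dev > k * sd
    outlying[:, zero_var] = False
    bad_rows = outlying.any(axis=1)
    excluded = list(tracts.values.index[bad_rows])
    kept = TractMatrix(tracts.values.loc[~bad_rows].copy(), tracts.measure)
    return kept, excluded


def first_pc_scores(matrix: pd.DataFrame) -> LatentScores:
    """Scores of the first unrotated principal component (correlation scale).

    Columns are standardized before the eigendecomposition, so the leading
    eigenvalue divided by the number of columns is the fraction of variance
    explained.  The component sign is chosen so the sum of loadings is
    positive, making score direction reproducible.

    Requires at least 2 columns, 3 complete-case rows and no missing values.
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.shape[1] < 2 or vals.shape[0] < 3:
        raise ValueError("need >= 2 columns and >= 3 subjects")
    if np.isnan(vals).any():
        raise ValueError("missing values present; filter to complete cases first")
    sd = vals.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column; cannot standardize")
    z = (vals - vals.mean(axis=0)) / sd
    corr = (z.T @ z) / (len(z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvals[-1]
    vec = eigvecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    scores = z @ vec
    return LatentScores(
        scores=pd.Series(scores, index=matrix.index),
        pct_variance=100.0 * float(lead) / vals.shape[1],
        loadings=pd.Series(vec, index=matrix.columns),
    )


def category_scores(tracts: TractMatrix, category: str) -> LatentScores:
    """First-component scores over one tract category's columns only."""
    if category not in _tracts.CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return first_pc_scores(tracts.category_columns(category))


def global_scores(tracts: TractMatrix) -> LatentScores:
    """First-component scores over all 27 columns (the global factor)."""
    return first_pc_scores(tracts.values)
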