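"""Joint association models for the two polygenic scores and FDR correction.

Every model includes both the pathway PRS and the rest-of-genome PRS as
predictors together with the fixed covariate set (age, age squared, sex, 15
genetic principal components, three scanner head-position coordinates and
the genotype array indicator).  Unilateral tracts and latent factors use
ordinary least squares; bilateral tracts use a repeated-measures linear
mixed model with a subject random intercept and a hemisphere fixed effect.
Benjamini-Hochberg correction is applied within declared families (the 15
individual tracts, or the 4 global + category factors, per measure and PRS
term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

PATHWAY = "pathway"
GENOMIC = "genomic"

#: Covariate columns expected in a covariate table; ``age_sq`` is derived.
COVARIATE_COLUMNS = (
    ["age", "sex"]
    + [f"pc{i}" for i in range(1, 16)]
    + ["head_x", "head_y", "head_z", "array"]
)


@dataclass
class AssociationResult:
    """One PRS term's estimate in one fitted model (standardized scale)."""

    term: str
    beta: float
    se: float
    t: float
    p: float
    r2_pct: float
    n: int
    p_fdr: float | None = None


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariate design block: adds age^2 next to age, passes the rest through."""
    design = covariates.copy()
    if "age" in design.columns and "age_sq" not in design.columns:
        design["age_sq"] = design["age"] ** 2
    return design


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # pivoted QR exposes which trailing columns are linearly dependent
        from scipy.linalg import qr

        _, _, piv = qr(mat, mode="economic", pivoting=True)
        dependent = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {dependent}")


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant outcome")
    return (v - v.mean()) / sd


def _adj_r2(model_fit) -> float:
    return float(model_fit.rsquared_adj)


def fit_unilateral(
    outcome: pd.Series,
    prs_pathway: pd.Series,
    prs_genomic: pd.Series,
    covariates: pd.DataFrame,
    r2_mode: str = "adjusted",
) -> dict[str, AssociationResult]:
    """OLS of a (standardized) outcome on both PRSs plus the covariates.

    Returns one :class:`AssociationResult` per PRS term.  ``r2_pct`` is 100
    times the increment in adjusted R-squared (or raw R-squared with
    ``r2_mode="raw"``) when the term is added to the model that already
    contains everything else; adjusted increments can be slightly negative.
    """
    if r2_mode not in ("adjusted", "raw"):
        raise ValueError("r2_mode must be 'adjusted' or 'raw'")
    idx = outcome.index
    y = _standardize(outcome.to_numpy(dtype=float))
    X = pd.DataFrame(
        {
            PATHWAY: prs_pathway.reindex(idx).to_numpy(dtype=float),
            GENOMIC: prs_genomic.reindex(idx).to_numpy(dtype=float),
        },
        index=idx,
    )
    X = pd.concat([X, build_design(covariates).reindex(idx)], axis=1)
    if X.isna().to_numpy().any():
        raise ValueError("design contains missing values; complete cases required")
    X = sm.add_constant(X, prepend=True)
    _check_full_rank(X)
    full = sm.OLS(y, X).fit()

    results: dict[str, AssociationResult] = {}
    for term in (PATHWAY, GENOMIC):
        reduced = sm.OLS(y, X.drop(columns=[term])).fit()
        if r2_mode == "adjusted":
            r2_inc = full.rsquared_adj - reduced.rsquared_adj
        else:
            r2_inc = full.rsquared - reduced.rsquared
        results[term] = AssociationResult(
            term=term,
            beta=float(full.params[term]),
            se=float(full.bse[term]),
            t=float(full.tvalues[term]),
            p=float(full.pvalues[term]),
            r2_pct=100.0 * float(r2_inc),
            n=len(y),
        )
    return results


def fit_bilateral(
    left: pd.Series,
    right: pd.Series,
    prs_pathway: pd.Series,
    prs_genomic: pd.Series,
    covariates: pd.DataFrame,
    r2_mode: str = "adjusted",
) -> dict[str, AssociationResult]:
    """Repeated-measures model for a bilateral tract (two rows per subject).

    Left and right hemisphere values are stacked (outcome standardized on
    the stacked vector) and fitted by a linear mixed model with a subject
    random intercept, a hemisphere fixed effect, both PRS terms and the
    covariates (REML).  Wald t statistics for the PRS terms use
    subject-level degrees of freedom: df = n_subjects - n_fixed_parameters,
    the conservative between-subject rule, since PRSs do not vary within
    subject.  ``r2_pct`` comes from the parallel stacked OLS (identical
    point estimates for between-subject terms under hemisphere balance).
    """
    if not left.index.equals(right.index):
        raise ValueError("left and right must cover the same subjects (2 rows each)")
    idx = left.index
    n_sub = len(idx)
    y = np.concatenate([left.to_numpy(dtype=float), right.to_numpy(dtype=float)])
    y = _standardize(y)
    hemi = np.concatenate([np.zeros(n_sub), np.ones(n_sub)])
    base = pd.DataFrame(
        {
            PATHWAY: prs_pathway.reindex(idx).to_numpy(dtype=float),
            GENOMIC: prs_genomic.reindex(idx).to_numpy(dtype=float),
        },
        index=idx,
    )
    base = pd.concat([base, build_design(covariates).reindex(idx)], axis=1)
    if base.isna().to_numpy().any():
        raise ValueError("design contains missing values; complete cases required")
    stacked = pd.concat([base, base], axis=0, ignore_index=True)
    stacked.insert(0, "hemisphere", hemi)
    X = sm.add_constant(stacked, prepend=True)
    _check_full_rank(X)
    groups = np.tile(np.arange(n_sub), 2)

    mixed = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
    df = n_sub - X.shape[1]
    if df <= 0:
        raise ValueError("not enough subjects for the fixed-effect design")

    # parallel stacked OLS for the variance-explained increments
    full_ols = sm.OLS(y, X).fit()
    results: dict[str, AssociationResult] = {}
    for term in (PATHWAY, GENOMIC):
        beta = float(mixed.fe_params[term])
        se = float(mixed.bse_fe[term])
        tval = beta / se
        p = 2.0 * float(sps.t.sf(abs(tval), df))
        reduced = sm.OLS(y, X.drop(columns=[term])).fit()
        if r2_mode == "adjusted":
            r2_inc = full_ols.rsquared_adj - reduced.rsquared_adj
        else:
            r2_inc = full_ols.rsquared - reduced.rsquared
        results[term] = AssociationResult(
            term=term,
            beta=beta,
            se=se,
            t=tval,
            p=p,
            r2_pct=100.0 * float(r2_inc),
            n=n_sub,
        )
    results["hemisphere"] = AssociationResult(
        term="hemisphere",
        beta=float(mixed.fe_params["hemisphere"]),
        se=float(mixed.bse_fe["hemisphere"]),
        t=float(mixed.fe_params["hemisphere"] / mixed.bse_fe["hemisphere"]),
        p=float(mixed.pvalues["hemisphere"]),
        r2_pct=float("nan"),
        n=n_sub,
    )
    return results


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: pd.DataFrame, family_cols=("measure", "term", "family")) -> pd.DataFrame:
    """Add a ``p_fdr`` column, adjusting within each declared family."""
    out = results.copy()
    out["p_fdr"] = np.nan
    for _, grp in out.groupby(list(family_cols), sort=False):
        out.loc[grp.index, "p_fdr"] = fdr_adjust(grp["p"].to_numpy())
    return out
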