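"""Multi-threshold weighted-allele polygenic scoring with optional LD clumping.

A subject's raw score at threshold *t* is the dosage-weighted sum of
ln(odds ratio) over the SNPs of the chosen set whose GWAS p value is <= t
(inclusive).  Columns are standardized to mean 0, SD 1 within the analysis
sample so downstream effect sizes are on the standardized scale.  Clumping
is the usual greedy scheme: visit SNPs by ascending GWAS p value and drop a
SNP that is within the window of an already-retained SNP on the same
chromosome with dosage r-squared above the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tractprs.config import PrsConfig


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele dosage matrix.

    Dosages are 0, 1 or 2 copies of the stated effect allele; missing calls
    are NaN and are mean-imputed per SNP at scoring time.
    """

    dosages: pd.DataFrame  # index: subject ids, columns: SNP ids

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def subjects(self) -> pd.Index:
        return self.dosages.index

    def imputed(self, snp_ids: list[str]) -> np.ndarray:
        """Dosage submatrix with per-SNP mean imputation of missing calls."""
        sub = self.dosages[snp_ids].to_numpy(dtype=float)
        if np.isnan(sub).any():
            col_means = np.nanmean(sub, axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            idx = np.where(np.isnan(sub))
            sub[idx] = col_means[idx[1]]
        return sub


@dataclass
class PRSProfile:
    """Standardized per-subject scores, one column per p-value threshold."""

    scores: pd.DataFrame  # index: subject ids, columns: thresholds
    snp_counts: dict[float, int]
    set_label: str
    nonstandardizable: set[float] = field(default_factory=set)
    raw: pd.DataFrame | None = None


def clump(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: PrsConfig | None = None,
) -> set[str]:
    """Greedy LD clump-based pruning; returns the retained SNP-id set.

    SNPs are visited by ascending GWAS p value, ties broken by
    (chrom, pos, id), so the result does not depend on input row order.
    LD is measured in-sample as the squared Pearson correlation of the
    (mean-imputed) dosage columns.
    """
    config = config or PrsConfig()
    config.validate()
    missing_cols = set(variants["id"].astype(str)) - set(map(str, genotypes.dosages.columns))
    if missing_cols:
        raise ValueError(
            "variants lack genotype columns: " + ", ".join(sorted(missing_cols)[:5])
        )
    order = variants.sort_values(
        ["p", "chrom", "pos", "id"], kind="mergesort"
    )
    ids = order["id"].astype(str).to_numpy()
    chroms = order["chrom"].astype(str).to_numpy()
    positions = order["pos"].to_numpy()

    dosage = genotypes.imputed(list(ids))
    # center once; r^2 between columns then reduces to dot products
    dosage = dosage - dosage.mean(axis=0)
    norms = np.sqrt((dosage**2).sum(axis=0))

    retained: list[int] = []
    retained_by_chrom: dict[str, list[int]] = {}
    for i in range(len(ids)):
        keep = True
        for j in retained_by_chrom.get(chroms[i], ()):
            if abs(positions[i] - positions[j]) > config.clump_window:
                continue
            denom = norms[i] * norms[j]
            if denom == 0:
                continue  # monomorphic column carries no LD
            r = float(dosage[:, i] @ dosage[:, j]) / denom
            if r * r > config.clump_r2:
                keep = False
                break
        if keep:
            retained.append(i)
            retained_by_chrom.setdefault(chroms[i], []).append(i)
    return {ids[i] for i in retained}


def compute_prs(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    snp_set: set[str],
    config: PrsConfig | None = None,
    set_label: str = "pathway",
) -> PRSProfile:
    """Compute standardized scores for one SNP set at every threshold.

    Pruning is the caller's responsibility (pass the clumped set through
    ``snp_set``), keeping this function a pure weighted sum.  Thresholds
    admitting zero SNPs (or a constant raw score) yield an all-zero column
    flagged in ``nonstandardizable``.
    """
    config = config or PrsConfig()
    config.validate()
    sel = variants[variants["id"].astype(str).isin(snp_set)].copy()
    if (sel["odds_ratio"] <= 0).any():
        bad = sel.loc[sel["odds_ratio"] <= 0, "id"].tolist()[:5]
        raise ValueError(f"odds ratios must be positive; offending SNPs: {bad}")
    sel = sel.drop_duplicates(subset="id")
    ids = sel["id"].astype(str).to_numpy()
    weights = np.log(sel["odds_ratio"].to_numpy(dtype=float))
    pvals = sel["p"].to_numpy(dtype=float)

    dosage = genotypes.imputed(list(ids)) if len(ids) else np.zeros(
        (len(genotypes.subjects), 0)
    )
    n = len(genotypes.subjects)
    raw_cols: dict[float, np.ndarray] = {}
    std_cols: dict[float, np.ndarray] = {}
    counts: dict[float, int] = {}
    flagged: set[float] = set()
    for t in config.thresholds:
        mask = pvals <= t
        counts[t] = int(mask.sum())
        raw = dosage[:, mask] @ weights[mask] if mask.any() else np.zeros(n)
        raw_cols[t] = raw
        sd = raw.std()
        if counts[t] == 0 or sd < 1e-12:
            if counts[t] == 0:
                warnings.warn(
                    f"threshold {t} admits no SNPs for set {set_label!r}",
                    stacklevel=2,
                )
            std_cols[t] = np.zeros(n)
            flagged.add(t)
        else:
            std_cols[t] = (raw - raw.mean()) / sd
    idx = genotypes.subjects
    return PRSProfile(
        scores=pd.DataFrame(std_cols, index=idx),
        snp_counts=counts,
        set_label=set_label,
        nonstandardizable=flagged,
        raw=pd.DataFrame(raw_cols, index=idx),
    )
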