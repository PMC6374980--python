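"""Circular genomic permutation null for pathway specificity.

All non-pathway genic SNPs are placed on a circle ordered by genomic
location.  The observed pathway SNP set is projected onto that circle as a
template of ranks that preserves its spacing pattern; each permutation
rotates the template by a random offset and scores the SNPs it lands on.
Because rotation preserves the template's gap multiset, permuted sets carry
the same genomic clustering (and hence LD-block co-membership) profile as
the pathway set, which is the point of circular permutation.  Each permuted
set is scored (threshold 0.5, unpruned), substituted for the pathway PRS in
the joint model (the rest-of-genome PRS stays in), and the |t| statistic of
its term recorded; the empirical p value is (1 + #{permuted >= observed}) /
(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tractprs.association import build_design
from tractprs.prs import GenotypeMatrix


@dataclass
class CircularGenome:
    """Ordered non-pathway genic SNPs plus the pathway spacing template."""

    snp_ids: list[str]  # circle order: (chromosome, position, id)
    template: np.ndarray  # k circle ranks encoding the pathway spacing

    @property
    def M(self) -> int:
        return len(self.snp_ids)

    @property
    def k(self) -> int:
        return len(self.template)


@dataclass
class PermutationNull:
    """Null distribution and empirical p value for one outcome."""

    outcome: str
    observed: float
    stats: np.ndarray
    p_emp: float
    observed_beta: float = float("nan")
    n_perm: int = 0

    def __post_init__(self) -> None:
        self.n_perm = len(self.stats)


def _chrom_sort_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, str(label))


def _genome_order(variants: pd.DataFrame, ids: set[str]) -> pd.DataFrame:
    sub = variants[variants["id"].astype(str).isin(ids)].copy()
    sub["id"] = sub["id"].astype(str)
    sub["_ckey"] = sub["chrom"].astype(str).map(_chrom_sort_key)
    sub = sub.sort_values(["_ckey", "pos", "id"], kind="mergesort")
    return sub.drop(columns="_ckey").reset_index(drop=True)


def build_circle(partition, variants: pd.DataFrame) -> CircularGenome:
    """Order non-pathway genic SNPs on the circle and project the pathway.

    Each pathway SNP maps to the circle rank of the nearest non-pathway
    genic SNP at or after its genomic position (wrapping past the end).
    Duplicate ranks -- two pathway SNPs whose nearest follower coincides --
    are advanced to the next free rank so the template keeps exactly k
    distinct positions and every rotation yields a size-k set.
    """
    genomic = _genome_order(variants, partition.genomic_snps)
    pathway = _genome_order(variants, partition.pathway_snps)
    M, k = len(genomic), len(pathway)
    if k == 0:
        raise ValueError("pathway SNP set is empty")
    if M <= k:
        raise ValueError(
            f"non-pathway genic SNP count ({M}) must exceed pathway count ({k})"
        )
    combined = pd.concat(
        [genomic.assign(_path=False), pathway.assign(_path=True)], ignore_index=True
    )
    combined = _genome_order(combined, set(combined["id"]))
    # recompute the pathway flag after reordering
    pathway_ids = set(pathway["id"])
    flags = combined["id"].isin(pathway_ids).to_numpy()
    # circle rank of each non-pathway row, then "next non-pathway rank" scan
    circle_rank = np.cumsum(~flags) - 1  # rank of the most recent non-pathway SNP
    next_rank = np.full(len(combined), -1, dtype=int)
    nxt = -1
    for i in range(len(combined) - 1, -1, -1):
        if not flags[i]:
            nxt = circle_rank[i]
        next_rank[i] = nxt
    # wrap: pathway SNPs after the last circle SNP map to rank 0
    next_rank[next_rank == -1] = 0
    raw_template = next_rank[flags]

    used: set[int] = set()
    template: list[int] = []
    for r in raw_template:
        r = int(r) % M
        while r in used:
            r = (r + 1) % M
        used.add(r)
        template.append(r)
    return CircularGenome(
        snp_ids=genomic["id"].tolist(),
        template=np.asarray(sorted(template), dtype=int),
    )


def set_at_offset(circle: CircularGenome, offset: int) -> set[str]:
    """SNP ids selected by rotating the template by ``offset`` (test hook)."""
    ranks = (circle.template + offset) % circle.M
    return {circle.snp_ids[r] for r in ranks}


def draw_permuted_sets(
    circle: CircularGenome,
    n_perm: int = 1000,
    seed: int = 0,
    contiguous: bool = False,
) -> list[set[str]]:
    """Rotate the template by ``n_perm`` distinct random offsets.

    Offsets are drawn uniformly without replacement from {1, ..., M-1} so no
    permuted list repeats and none equals the template's own projection.
    With ``contiguous=True`` the spacing template is replaced by a single
    block of k adjacent ranks (comparison mode).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm > circle.M - 1:
        raise ValueError(
            f"n_perm ({n_perm}) exceeds available offsets (M-1 = {circle.M - 1})"
        )
    rng = np.random.default_rng(seed)
    offsets = rng.choice(circle.M - 1, size=n_perm, replace=False) + 1
    base = circle
    if contiguous:
        base = CircularGenome(circle.snp_ids, np.arange(circle.k))
    return [set_at_offset(base, int(d)) for d in offsets]


def permutation_pvalue(observed: float, stats) -> float:
    """Add-one empirical p value: (1 + #{stats >= observed}) / (n + 1)."""
    stats = np.asarray(stats, dtype=float)
    if stats.size == 0:
        raise ValueError("stats must be nonempty")
    if not np.isfinite(stats).all() or not np.isfinite(observed):
        raise ValueError("non-finite statistic")
    return float((1 + np.sum(stats >= observed)) / (stats.size + 1))


# ---------------------------------------------------------------------------
# fast exact-OLS engine for the permuted refits


class _FastJointModel:
    """Exact OLS |t| of a candidate PRS term, all other terms residualized.

    By Frisch-Waugh-Lovell, the t statistic of x in y ~ x + W equals the t
    from regressing the W-residualized y on the W-residualized x with the
    full model's residual degrees of freedom, so refitting per permutation
    reduces to a few matrix-vector products against a precomputed QR basis.
    """

    def __init__(self, outcome: np.ndarray, W: np.ndarray):
        self.n = len(outcome)
        self.p_full = W.shape[1] + 1
        q, _ = np.linalg.qr(W)
        self._q = q
        y = outcome - outcome.mean()
        y = y / y.std()
        self.y_resid = y - q @ (q.T @ y)
        self._yss = float(self.y_resid @ self.y_resid)

    def t_stats(self, X: np.ndarray) -> np.ndarray:
        """|t| for each column of X as the candidate term (vectorized)."""
        Xr = X - self._q @ (self._q.T @ X)
        xss = (Xr * Xr).sum(axis=0)
        xy = Xr.T @ self.y_resid
        df = self.n - self.p_full
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = xy / xss
            rss = self._yss - beta * xy
            sigma2 = rss / df
            t = beta / np.sqrt(sigma2 / xss)
        return np.abs(np.where(xss > 1e-12, t, 0.0))


@dataclass
class OutcomeSpec:
    """Phenotype entering the permutation analysis.

    ``values`` is a subject-level series for unilateral tracts and latent
    factors, or a (left, right) pair for bilateral tracts, in which case the
    hemispheres are averaged to the subject level: with balanced repeated
    measures the between-subject PRS estimate of the random-intercept model
    equals the subject-mean OLS estimate, so the collapsed statistic is the
    same test applied identically to observed and permuted scores.
    """

    name: str
    values: pd.Series | tuple[pd.Series, pd.Series]

    def subject_level(self) -> pd.Series:
        if isinstance(self.values, tuple):
            left, right = self.values
            if not left.index.equals(right.index):
                raise ValueError("left/right subject mismatch")
            return (left + right) / 2.0
        return self.values


def run_permutation_analysis(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    partition,
    outcomes: list[OutcomeSpec],
    covariates: pd.DataFrame,
    prs_genomic: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    contiguous: bool = False,
) -> dict[str, PermutationNull]:
    """Full circular-permutation pass over the given outcomes.

    For every permuted set: score it at the primary threshold (unpruned),
    standardize, substitute it for the pathway PRS in the joint model (the
    rest-of-genome PRS and all covariates retained) and record |t|; the
    observed statistic is computed by the same engine with the real pathway
    PRS.
    """
    circle = build_circle(partition, variants)
    perm_sets = draw_permuted_sets(circle, n_perm, seed, contiguous=contiguous)

    vsub = variants.copy()
    vsub["id"] = vsub["id"].astype(str)
    vinfo = vsub.set_index("id")
    if (vinfo.loc[list(partition.pathway_snps | partition.genomic_snps), "odds_ratio"] <= 0).any():
        raise ValueError("odds ratios must be positive")

    def _score(snp_ids: set[str]) -> np.ndarray:
        ids = [s for s in snp_ids if vinfo.loc[s, "p"] <= threshold]
        if not ids:
            return np.zeros(len(genotypes.subjects))
        dose = genotypes.imputed(ids)
        w = np.log(vinfo.loc[ids, "odds_ratio"].to_numpy(dtype=float))
        return dose @ w

    # weighted dosage columns for all circle SNPs passing the threshold
    circle_ids = circle.snp_ids
    keep_w = np.where(
        vinfo.loc[circle_ids, "p"].to_numpy(dtype=float) <= threshold,
        np.log(vinfo.loc[circle_ids, "odds_ratio"].to_numpy(dtype=float)),
        0.0,
    )
    weighted = genotypes.imputed(circle_ids) * keep_w

    rank_sets = []
    id_to_rank = {s: r for r, s in enumerate(circle_ids)}
    for s in perm_sets:
        rank_sets.append(np.fromiter((id_to_rank[i] for i in s), dtype=int))

    def _standardize_cols(mat: np.ndarray) -> np.ndarray:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return (mat - mu) / sd

    perm_scores = np.column_stack(
        [weighted[:, ranks].sum(axis=1) for ranks in rank_sets]
    )
    perm_scores = _standardize_cols(perm_scores)

    observed_raw = _score(partition.pathway_snps)
    observed_prs = _standardize_cols(observed_raw[:, None])[:, 0]

    design = build_design(covariates)
    results: dict[str, PermutationNull] = {}
    for spec in outcomes:
        y = spec.subject_level()
        idx = y.index
        W = np.column_stack(
            [
                np.ones(len(idx)),
                prs_genomic.reindex(idx).to_numpy(dtype=float),
                design.reindex(idx).to_numpy(dtype=float),
            ]
        )
        if np.isnan(W).any():
            raise ValueError(f"missing covariate values for outcome {spec.name!r}")
        engine = _FastJointModel(y.to_numpy(dtype=float), W)
        pos = {s: i for i, s in enumerate(genotypes.subjects)}
        rows = np.fromiter((pos[s] for s in idx), dtype=int)
        try:
            obs_t = float(engine.t_stats(observed_prs[rows, None])[0])
            null_t = engine.t_stats(perm_scores[rows, :])
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"model fit failed for outcome {spec.name!r}") from exc
        # standardized beta of the observed pathway term for the report
        xr = observed_prs[rows] - engine._q @ (engine._q.T @ observed_prs[rows])
        xss = float(xr @ xr)
        obs_beta = float((xr @ engine.y_resid) / xss) if xss > 0 else 0.0
        results[spec.name] = PermutationNull(
            outcome=spec.name,
            observed=obs_t,
            stats=null_t,
            p_emp=permutation_pvalue(obs_t, null_t),
            observed_beta=obs_beta,
        )
    return results
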