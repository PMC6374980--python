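"""Synthetic cohort generator.

Produces all inputs the pipeline consumes, with the statistical structure
the analysis assumes, so every downstream stage can be exercised without
real data:

* a gene map with non-overlapping transcription intervals and wide
  inter-gene gaps (so intergenic SNPs exist), plus a pathway gene subset;
* effect-allele dosages with block LD from a haplotype-copying model: within
  a block each haplotype allele is copied from the previous SNP with
  probability ``ld_rho`` and redrawn at the block MAF otherwise, giving
  adjacent-SNP haplotype correlation exactly ``ld_rho`` and independence
  across blocks;
* marginal GWAS summary statistics: per-SNP true log-odds effects drawn with
  a larger SD inside pathway genes (pathway enrichment), observed effects
  with sampling noise SE = 1/sqrt(gwas_n * 2 * maf * (1 - maf)), odds
  ratios, and two-sided normal p values;
* covariates (age, sex, 15 orthonormal genetic PCs, head position,
  genotype array) and a factor-structured tract matrix: each tract loads on
  a global factor and its category factor, bilateral tracts share the
  subject-level signal across hemispheres, and configured pathway-PRS
  effects are planted on named (tract, measure) outcomes.

Every operation derives its random stream from ``config.seed`` plus a fixed
stage tag, so identical configurations reproduce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from tractprs import tracts as _tracts
from tractprs.annotate import SnpPartition, annotate_snps, partition_by_pathway
from tractprs.config import DEFAULT_FLANK, PrsConfig, SimulationConfig
from tractprs.phenotypes import TractMatrix
from tractprs.prs import GenotypeMatrix, PRSProfile, compute_prs

_STAGE = {"gene_map": 1, "genotypes": 2, "sumstats": 3, "covariates": 4, "phenotypes": 5}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


def simulate_gene_map(config: SimulationConfig) -> tuple[pd.DataFrame, list[str]]:
    """Place genes on chromosomes and pick the pathway subset.

    Genes are laid out sequentially per chromosome with alternating wide and
    narrow gaps; wide gaps exceed twice the default annotation flank, so at
    least half of the inter-gene space is intergenic at flank 20 kb.
    Intervals never overlap by construction.  The pathway is a without-
    replacement sample of ``pathway_n_genes`` gene names.
    """
    config.validate()
    rng = _rng(config, "gene_map")
    names = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    chroms = [str(1 + i % config.n_chromosomes) for i in range(config.n_genes)]
    rows = []
    cursor: dict[str, int] = {}
    for name, chrom, i in zip(names, chroms, range(config.n_genes)):
        length = int(rng.integers(5_000, 100_000))
        wide = (i // config.n_chromosomes) % 2 == 0
        if wide:
            gap = int(rng.integers(2 * DEFAULT_FLANK + 10_000, 2 * DEFAULT_FLANK + 120_000))
        else:
            gap = int(rng.integers(2_000, 30_000))
        start = cursor.get(chrom, 1) + gap
        end = start + length
        if start < 1:
            raise ValueError("gene placement failed: negative coordinate")
        rows.append({"gene": name, "chrom": chrom, "tx_start": start, "tx_end": end})
        cursor[chrom] = end
    gene_map = pd.DataFrame(rows)
    pathway = sorted(
        rng.choice(np.array(names), size=config.pathway_n_genes, replace=False)
    )
    return gene_map, list(pathway)


def simulate_genotypes(
    config: SimulationConfig, gene_map: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Dosage matrix with block LD plus the SNP position table.

    SNP positions are uniform over each chromosome's occupied span (plus a
    flank-sized margin), landing both inside and between genes.  LD blocks
    are runs of ``ld_block_size`` consecutive SNPs that never straddle a
    chromosome boundary; all SNPs in a block share one MAF drawn from
    ``maf_range`` so the copying process leaves marginal frequencies intact.
    """
    config.validate()
    lo, hi = config.maf_range
    if not (0 < lo and hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = _rng(config, "genotypes")

    spans = gene_map.groupby("chrom")["tx_end"].max()
    chrom_labels = sorted(spans.index, key=lambda c: int(c))
    weights = np.array([spans[c] for c in chrom_labels], dtype=float)
    counts = np.floor(config.n_snps * weights / weights.sum()).astype(int)
    counts[: config.n_snps - counts.sum()] += 1

    rows = []
    for chrom, cnt in zip(chrom_labels, counts):
        if cnt == 0:
            continue
        top = int(spans[chrom]) + DEFAULT_FLANK
        pos = np.sort(rng.choice(top, size=cnt, replace=False) + 1)
        for p in pos:
            rows.append((chrom, int(p)))
    variants = pd.DataFrame(rows, columns=["chrom", "pos"])
    variants.insert(0, "id", [f"snp{i:06d}" for i in range(1, len(variants) + 1)])
    variants["ref"] = "A"
    variants["alt"] = "G"
    variants["effect_allele"] = "G"

    # block index restarts at each chromosome boundary
    block = np.zeros(len(variants), dtype=int)
    b = -1
    prev_chrom, in_block = None, 0
    for i, chrom in enumerate(variants["chrom"]):
        if chrom != prev_chrom or in_block == config.ld_block_size:
            b += 1
            in_block = 0
            prev_chrom = chrom
        block[i] = b
        in_block += 1
    n_blocks = b + 1
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    maf = block_maf[block]
    variants["maf"] = maf
    new_block = np.ones(len(variants), dtype=bool)
    new_block[1:] = block[1:] != block[:-1]

    n_hap = 2 * config.n_subjects
    fresh = rng.random((n_hap, len(variants))) < maf
    copy = rng.random((n_hap, len(variants))) < config.ld_rho
    copy[:, new_block] = False
    alleles = np.empty((n_hap, len(variants)), dtype=bool)
    alleles[:, 0] = fresh[:, 0]
    for j in range(1, len(variants)):
        alleles[:, j] = np.where(copy[:, j], alleles[:, j - 1], fresh[:, j])
    dosage = (alleles[0::2].astype(np.int8) + alleles[1::2]).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    subjects = [f"S{i:06d}" for i in range(1, config.n_subjects + 1)]
    geno = GenotypeMatrix(
        pd.DataFrame(dosage, index=subjects, columns=variants["id"].tolist())
    )
    return geno, variants


def simulate_gwas_sumstats(
    config: SimulationConfig,
    variants: pd.DataFrame,
    pathway_membership: set[str],
) -> pd.DataFrame:
    """Attach odds ratios, standard errors and p values to the SNP table.

    True log-odds effects are N(0, pathway_effect_sd^2) for SNPs in
    ``pathway_membership`` and N(0, genomic_effect_sd^2) otherwise; the
    observed log-odds adds sampling noise with the usual GWAS standard error
    for an allele of the SNP's frequency at ``gwas_n`` samples.
    """
    config.validate()
    rng = _rng(config, "sumstats")
    maf = variants["maf"].to_numpy(dtype=float)
    if ((maf <= 0) | (maf >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    in_path = variants["id"].astype(str).isin(pathway_membership).to_numpy()
    sd = np.where(in_path, config.pathway_effect_sd, config.genomic_effect_sd)
    true = rng.normal(0.0, 1.0, size=len(variants)) * sd
    se = 1.0 / np.sqrt(config.gwas_n * 2.0 * maf * (1.0 - maf))
    obs = true + rng.normal(0.0, 1.0, size=len(variants)) * se
    z = obs / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    out = variants.copy()
    out["odds_ratio"] = np.exp(obs)
    out["se"] = se
    out["p"] = p
    out["true_logodds"] = true
    return out


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Covariate table: age, sex, 15 orthonormal genetic PCs (scaled to unit
    variance), three head-position coordinates and a binary array indicator."""
    config.validate()
    rng = _rng(config, "covariates")
    n = config.n_subjects
    subjects = [f"S{i:06d}" for i in range(1, n + 1)]
    cov = pd.DataFrame(index=pd.Index(subjects, name="subject"))
    cov["age"] = rng.uniform(45.0, 79.0, size=n)
    cov["sex"] = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.normal(size=(n, 15))
    q, _ = np.linalg.qr(pcs)
    q = q * np.sqrt(n)  # orthonormal columns rescaled to unit variance
    for i in range(15):
        cov[f"pc{i + 1}"] = q[:, i]
    for axis in ("x", "y", "z"):
        cov[f"head_{axis}"] = rng.normal(size=n)
    cov["array"] = (rng.random(n) < 0.1).astype(float)
    return cov


def simulate_phenotypes(
    config: SimulationConfig,
    prs_pathway: pd.Series,
    prs_genomic: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[dict[str, TractMatrix], pd.DataFrame]:
    """Factor-structured tract matrices (FA and MD) with planted PRS effects.

    Each tract's subject-level signal is

        loading_global * G + loading_category * C_cat
        + planted_beta * PRS_pathway + covariate effects,

    with G and the three category factors standard normal across subjects.
    Bilateral tracts share the subject-level signal plus a shared noise
    component sized so the left/right correlation of the noise equals
    ``hemisphere_rho``; hemisphere-specific noise makes up the rest.
    Covariate effects (default zero) apply to z-scored covariate columns.
    """
    config.validate()
    rng = _rng(config, "phenotypes")
    if covariates is None:
        covariates = simulate_covariates(config)
    idx = covariates.index
    n = len(idx)
    path = prs_pathway.reindex(idx).to_numpy(dtype=float)
    gen = prs_genomic.reindex(idx).to_numpy(dtype=float)
    if np.isnan(path).any() or np.isnan(gen).any():
        raise ValueError("PRS vectors must cover all subjects")

    cov_effect = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        col = covariates[name].to_numpy(dtype=float)
        colsd = col.std()
        z = (col - col.mean()) / colsd if colsd > 0 else np.zeros(n)
        cov_effect = cov_effect + beta * z

    s = config.tract_noise_sd
    shared_sd = s * np.sqrt(config.hemisphere_rho)
    hemi_sd = s * np.sqrt(1.0 - config.hemisphere_rho)

    matrices: dict[str, TractMatrix] = {}
    for measure in _tracts.MEASURES:
        G = rng.normal(size=n)
        C = {cat: rng.normal(size=n) for cat in _tracts.CATEGORIES}
        cols: dict[tuple[str, str], np.ndarray] = {}
        for t in _tracts.TRACTS:
            beta = config.planted_beta.get((t.name, measure), 0.0)
            beta_g = config.planted_beta_genomic.get((t.name, measure), 0.0)
            signal = (
                config.tract_loading_global * G
                + config.tract_loading_category * C[t.category]
                + beta * path
                + beta_g * gen
                + cov_effect
            )
            if t.bilateral:
                shared = rng.normal(size=n) * shared_sd
                cols[(t.name, _tracts.LEFT)] = (
                    signal + shared + rng.normal(size=n) * hemi_sd
                )
                cols[(t.name, _tracts.RIGHT)] = (
                    signal + shared + rng.normal(size=n) * hemi_sd
                )
            else:
                cols[(t.name, _tracts.MIDLINE)] = signal + rng.normal(size=n) * s
        values = pd.DataFrame(cols, index=idx)
        values.columns = pd.MultiIndex.from_tuples(
            values.columns, names=["tract", "hemisphere"]
        )
        matrices[measure] = TractMatrix(values, measure)
    return matrices, covariates


@dataclass
class Cohort:
    """Everything one simulated analysis run needs, bundled."""

    config: SimulationConfig
    gene_map: pd.DataFrame
    pathway_genes: list[str]
    genotypes: GenotypeMatrix
    variants: pd.DataFrame  # with summary statistics
    partition: SnpPartition
    prs_pathway: PRSProfile
    prs_genomic: PRSProfile
    covariates: pd.DataFrame
    tract_matrices: dict[str, TractMatrix]


def simulate_cohort(
    config: SimulationConfig,
    flank: int = DEFAULT_FLANK,
    prs_config: PrsConfig | None = None,
    planting_threshold: float = 0.5,
) -> Cohort:
    """Full chain: gene map -> genotypes -> GWAS -> partition -> PRS -> tracts.

    The planted tract effects use the standardized unpruned scores at
    ``planting_threshold`` (the primary analysis threshold), so a downstream
    fit at that threshold targets exactly the planted coefficients.
    """
    prs_config = prs_config or PrsConfig()
    gene_map, pathway_genes = simulate_gene_map(config)
    genotypes, positions = simulate_genotypes(config, gene_map)
    assignments = annotate_snps(positions, gene_map, flank=flank)
    partition = partition_by_pathway(
        assignments, set(pathway_genes), set(gene_map["gene"])
    )
    variants = simulate_gwas_sumstats(config, positions, partition.pathway_snps)
    prof_path = compute_prs(
        genotypes, variants, partition.pathway_snps, prs_config, set_label="pathway"
    )
    prof_gen = compute_prs(
        genotypes, variants, partition.genomic_snps, prs_config, set_label="genomic"
    )
    matrices, covariates = simulate_phenotypes(
        config,
        prof_path.scores[planting_threshold],
        prof_gen.scores[planting_threshold],
    )
    return Cohort(
        config=config,
        gene_map=gene_map,
        pathway_genes=pathway_genes,
        genotypes=genotypes,
        variants=variants,
        partition=partition,
        prs_pathway=prof_path,
        prs_genomic=prof_gen,
        covariates=covariates,
        tract_matrices=matrices,
    )
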