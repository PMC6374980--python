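# Methods

This note documents the statistical model the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## The analysis model

### SNP annotation and partition

A SNP belongs to a gene when its position lies inside the gene's
transcription interval extended by a flank (default 20,000 bases) on both
sides.  Coordinates are 1-based and intervals closed; boundary positions
count as inside.  Extended intervals clamp at position 1; no
chromosome-length clamp is applied because tract lengths are unknown to the
tool.  Strand is ignored: the extension is symmetric from the stored
tx_start/tx_end.  SNPs in no extended gene are intergenic and excluded from
both scores.  A SNP overlapping both a pathway gene and a non-pathway gene
is assigned to the pathway set only, keeping the two scoring sets disjoint —
the analysis requires the rest-of-genome score to exclude pathway variation,
and disjointness is the conservative reading.  Each SNP is scored once per
set regardless of how many genes it hits.

### Polygenic scores

The raw score of subject *i* at threshold *t* is
`Σ_j d_ij · ln(OR_j)` over the SNPs of the set with GWAS p ≤ t (inclusive
comparison; boundary-tested).  ln(OR) is used because "weight by strength of
association" on odds-ratio summary statistics conventionally means the
log-odds scale.  Missing dosages are mean-imputed per SNP before summation.
Each threshold column is standardized (mean 0, SD 1, population SD) within
the analysis sample, so downstream effects are standardized betas; a
threshold admitting zero SNPs (or a constant raw score) yields an all-zero
column flagged non-standardizable.  Clump-based pruning is the standard
greedy scheme — visit SNPs by ascending p (ties broken by chromosome,
position, id), retain unless within 250 kb of a retained same-chromosome SNP
with dosage r² > 0.25 — computed from in-sample dosage correlation; no
external LD reference is consulted.  The primary analysis path is the
unpruned score at t = 0.5; pruning is a flag.

### Phenotype reduction

Outlier exclusion is per modality: a subject is dropped when any of their 27
tract columns lies strictly outside mean ± k·SD (k = 3) of that column,
with means and SDs computed once on the unfiltered sample (not iterated).
The rule operates per tract column rather than on the global factor — the
source description is ambiguous, and the per-column reading is the stricter
and more common quality-control practice.  With 27 correlated near-Gaussian
columns this excludes a few percent of subjects; real tract data, whose
outliers concentrate in a few subjects, loses fewer.

Latent factors are first unrotated principal components of the standardized
columns (correlation-scale PCA), because tract columns have heterogeneous
scales and the variance-explained percentages of correlation PCA are the
interpretable ones.  The component sign is fixed so the sum of loadings is
positive: a higher global score means globally higher FA (or MD).  Note
that this makes the orientation a property of the data direction — negating
the input matrix leaves the loadings unchanged (the correlation matrix is
invariant) and negates the scores.  `pct_variance` is 100 × leading
eigenvalue / number of columns.

### Association models

All models contain both PRS terms plus the fixed covariate block: age, age²,
sex, 15 genetic principal components, head position X/Y/Z, genotype array.
Outcomes and PRSs are standardized, so betas are comparable across outcomes
(real-data effects of this design are of order 0.03).

* Unilateral tracts and latent factors: ordinary least squares; per-term t
  and two-sided p from the t distribution.
* Bilateral tracts: hemisphere-stacked repeated-measures linear mixed model
  with a subject random intercept and hemisphere fixed effect, fitted by
  REML.  The PRS Wald t uses subject-level degrees of freedom,
  df = n_subjects − n_fixed_parameters: PRSs do not vary within subject, so
  between-subject df is the conservative and appropriate rule (the exact
  df convention is otherwise unstated in the source design).

`r2_pct`, the % variance explained by one PRS term, is 100 × the increment
in **adjusted** R² when the term is added to the otherwise-full model.
Adjusted increments were chosen because the published tables contain small
negative R² values, impossible for raw increments but natural for adjusted
ones; a raw-increment mode is available by flag.  For bilateral outcomes the
increment is computed on the parallel stacked OLS, whose point estimates
coincide with the mixed model's for between-subject terms under hemisphere
balance.

FDR correction is Benjamini–Hochberg, applied separately within each family:
the 15 individual tracts, and the 4 global+category factors, per measure and
per PRS term (family sizes m = 15 and m = 4 reproduce the published
adjusted values).

### Circular genomic permutation

Non-pathway genic SNPs are ordered by (chromosome, position, id) and joined
end-to-start into a circle of size M.  The observed pathway SNP set (size k)
is projected onto the circle as a template: each pathway SNP maps to the
rank of the nearest following non-pathway SNP; duplicate ranks advance to
the next free rank so the template always has k distinct positions.  Each
permutation rotates the template by an offset drawn uniformly **without
replacement** from {1, …, M−1}, so no null list repeats and none equals the
template's own projection.  Spacing-preserving rotation (rather than
contiguous blocks, available behind a flag) is the default because rotation
preserves the template's gap multiset and hence the pathway's genomic
clustering and LD-block co-membership profile — the stated purpose of
circular permutation.  Each null set is scored at the primary threshold
(unpruned), standardized, and substituted for the pathway PRS in the joint
model; the statistic is |t| of that term.  The empirical p uses the add-one
estimator (1 + r)/(1 + n_perm), which cannot return zero and is exact under
exchangeability.

For speed, permuted refits use the Frisch–Waugh–Lovell identity: with the
covariates, intercept and genomic PRS residualized out once by QR, the exact
OLS t of each candidate score is a few matrix–vector products, so 1000
permutations cost about as much as one model fit.  Bilateral outcomes enter
the permutation analysis as subject-level hemisphere means, for both the
observed and the permuted statistic.  With balanced two-hemisphere data, the
between-subject PRS estimate of the random-intercept model equals the
subject-mean OLS estimate, and because the identical statistic is applied to
observed and permuted scores the permutation test remains exact regardless;
the Table-style report still carries the mixed-model beta and t for the
observed fit.

## The synthetic-data generator

The generator emulates, at configurable scale, the structure the analysis
assumes:

* **Gene map** — non-overlapping transcription intervals laid out
  sequentially per chromosome, alternating wide (> 2 × 20 kb) and narrow
  gaps so intergenic SNPs exist at the default flank; the pathway is a
  random gene subset (default 43 genes, the size of the NETRIN1 pathway).
* **Genotypes** — haplotype-copying LD: within a block of `ld_block_size`
  consecutive SNPs (blocks never straddle chromosomes), each haplotype
  allele copies the previous SNP's allele with probability `ld_rho` (default
  0.8), else is redrawn at the block MAF.  All SNPs of a block share one MAF
  (drawn from `maf_range`, default 0.05–0.5) so copying leaves marginal
  frequencies intact; adjacent-SNP haplotype correlation is exactly
  `ld_rho`, and cross-block correlation is zero.  This was chosen over a
  coalescent simulation because it is tunable and analytically checkable.
* **GWAS summary statistics** — simulated marginally (no case/control
  genotypes, matching what the pipeline consumes): true per-SNP log-odds
  effects N(0, sd²) with sd 0.005 inside pathway genes and 0.002 elsewhere
  (pathway enrichment; values chosen so per-SNP |z| sits near the detection
  boundary at the default GWAS size, as for a polygenic trait), observed
  effects add noise with SE = 1/√(gwas_n · 2·maf·(1−maf)) at
  gwas_n = 461,134 (the size of the reference MDD GWAS), p values from the
  two-sided normal statistic.  The case fraction of the underlying GWAS is
  not modelled; everything lives on the log-odds scale.
* **Phenotypes** — each tract value is
  `g·G + c·C_cat + β_planted·PRS_pathway + covariate effects + noise`, with
  G and category factors standard normal, defaults g = 0.6, c = 0.4, noise
  SD 0.65 (set so the global factor explains ≈ 38% of variance, the level
  reported for real tract data).  Bilateral tracts share the subject-level
  signal plus a shared noise component sized so the noise's left/right
  correlation is `hemisphere_rho` (default 0.7 — high but imperfect
  agreement, the structure the repeated-measures model exploits).  The
  default planted effects mirror the published significant pattern (e.g.
  −0.035 on superior longitudinal fasciculus FA); covariate effects default
  to zero but are configurable so adjustment code paths are exercised.
* **Covariates** — age uniform 45–79 (the imaged cohort's range), sex
  Bernoulli(½), 15 exactly orthonormal genetic PCs scaled to unit variance,
  standard-normal head positions, array indicator Bernoulli(0.1).

Each operation derives its random stream from `seed` plus a fixed stage tag,
so identical configurations reproduce byte-identical cohorts, per stage and
end to end.

**What a green test does not establish:** the generator has no recombination
map, no imputation artifacts, no array batch effects, no population
stratification (the PCs are pure noise), no missing-not-at-random genotypes
and no heavy-tailed imaging outliers; planted effects are linear and
homoscedastic.  Tests on synthetic cohorts validate the pipeline's
arithmetic, calibration and power under its own assumptions — not the
robustness of those assumptions to real data.

## Numerical conventions and degenerate inputs

* Standardization uses population SD (ddof = 0); PCA column standardization
  uses sample SD (ddof = 1) for the correlation matrix.
* Thresholds compare inclusively (p ≤ t); clumping triggers strictly
  (r² > 0.25); outliers are strict (> k·SD).
* Monomorphic dosage columns carry no LD (their correlation is undefined and
  treated as no-clump) and produce zero-variance score contributions.
* p values from the GWAS simulator are clipped into (0, 1] at the smallest
  positive double.
* Tie-breaks: clumping visits equal-p SNPs by (chromosome, position, id);
  circle ordering is (numeric chromosome, position, id).
* Degenerate repeated measures (left ≡ right) reduce to the unilateral OLS
  estimates; a subject-count mismatch between hemispheres is an error.
* Rank-deficient association designs fail loudly, naming the collinear
  columns found by pivoted QR.

## Known limitations

* In-sample LD for clumping (no reference panel option).
* The mixed model's df rule is one defensible convention among several;
  p values for bilateral tracts shift slightly under alternatives.
* The permutation stage models bilateral outcomes at the subject level (see
  above); an option to refit the full mixed model per permutation would be
  ~100× slower and is not implemented.
* Multi-allelic sites are treated as independent rows keyed by id; no
  allele matching or strand flipping beyond exact string equality (a
  mismatch is an error, not a silent drop).
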