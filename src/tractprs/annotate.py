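"""Gene-based SNP annotation and pathway partitioning.

SNPs are assigned to every gene whose flank-extended transcription interval
contains their position (default flank 20 kb on each side); SNPs that land in
no extended gene are intergenic and are dropped.  Genic SNPs are then split
into a pathway set (assigned to at least one pathway gene) and a
rest-of-genome set, which stay disjoint so the two polygenic scores never
share a SNP.

Coordinates are 1-based with closed intervals; boundary positions are
inside.  Extended intervals clamp at position 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pyranges as pr

from tractprs.config import DEFAULT_FLANK

GENE_MAP_COLUMNS = ("gene", "chrom", "tx_start", "tx_end")
VARIANT_COLUMNS = (
    "id", "chrom", "pos", "ref", "alt", "effect_allele", "odds_ratio", "se", "p",
)


@dataclass(frozen=True)
class GeneInterval:
    """One gene's transcription interval (1-based, closed)."""

    name: str
    chrom: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start < 1 or self.tx_end < self.tx_start:
            raise ValueError(
                f"invalid interval for {self.name}: [{self.tx_start}, {self.tx_end}]"
            )


@dataclass
class SnpPartition:
    """Disjoint, exhaustive split of the input SNP ids.

    ``pathway_snps`` and ``genomic_snps`` partition the genic SNPs;
    ``dropped_intergenic`` holds the rest.  ``assignments`` records every
    gene each genic SNP was annotated to.
    """

    pathway_snps: set[str]
    genomic_snps: set[str]
    dropped_intergenic: set[str]
    assignments: dict[str, list[str]]


def extend_gene_bounds(
    gene: GeneInterval, flank: int = DEFAULT_FLANK
) -> tuple[int, int]:
    """Extended closed interval [max(1, tx_start - flank), tx_end + flank]."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return max(1, gene.tx_start - flank), gene.tx_end + flank


def annotate_snps(
    variants: pd.DataFrame,
    gene_map: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
) -> dict[str, list[str]]:
    """Map every SNP id to the (possibly empty) list of genes it falls in.

    A SNP is assigned to each gene whose flank-extended interval on the same
    chromosome contains its position, boundaries included.  An empty gene
    list marks the SNP as intergenic.  Chromosome labels present among the
    variants but absent from the gene map trigger a warning, not an error.

    Parameters
    ----------
    variants
        Table with at least ``id``, ``chrom``, ``pos`` columns.
    gene_map
        Table with ``gene``, ``chrom``, ``tx_start``, ``tx_end`` columns.
    flank
        Bases added on each side of the transcription interval.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    missing = set(variants["chrom"].astype(str)) - set(gene_map["chrom"].astype(str))
    if missing:
        warnings.warn(
            "variant chromosomes absent from gene map: "
            + ", ".join(sorted(missing)),
            stacklevel=2,
        )

    starts = (gene_map["tx_start"] - flank).clip(lower=1)
    ends = gene_map["tx_end"] + flank
    genes_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": gene_map["chrom"].astype(str).to_numpy(),
                # half-open 0-based for pyranges; closed 1-based [s, e] -> [s-1, e)
                "Start": starts.to_numpy() - 1,
                "End": ends.to_numpy(),
                "gene": gene_map["gene"].to_numpy(),
            }
        )
    )
    snps_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": variants["chrom"].astype(str).to_numpy(),
                "Start": variants["pos"].to_numpy() - 1,
                "End": variants["pos"].to_numpy(),
                "snp": variants["id"].to_numpy(),
            }
        )
    )
    joined = snps_pr.join(genes_pr)
    assignments: dict[str, list[str]] = {str(s): [] for s in variants["id"]}
    if len(joined) > 0:
        for snp, gene in zip(joined.df["snp"], joined.df["gene"]):
            assignments[str(snp)].append(str(gene))
    for lst in assignments.values():
        lst.sort()
    return assignments


def partition_by_pathway(
    assignments: dict[str, list[str]],
    pathway_genes: set[str],
    gene_names: set[str] | None = None,
) -> SnpPartition:
    """Split annotated SNPs into pathway and rest-of-genome sets.

    A SNP annotated to at least one pathway gene belongs to the pathway set
    even if it also overlaps non-pathway genes, keeping the two sets
    disjoint.  SNPs with no gene assignment are recorded as dropped
    intergenic SNPs.

    Raises ``ValueError`` if ``pathway_genes`` contains names absent from
    ``gene_names`` (when a gene-name universe is supplied).
    """
    if gene_names is not None:
        unknown = set(pathway_genes) - set(gene_names)
        if unknown:
            raise ValueError(
                "pathway genes missing from gene map: " + ", ".join(sorted(unknown))
            )
    pathway: set[str] = set()
    genomic: set[str] = set()
    intergenic: set[str] = set()
    genic_assignments: dict[str, list[str]] = {}
    for snp, genes in assignments.items():
        if not genes:
            intergenic.add(snp)
            continue
        genic_assignments[snp] = list(genes)
        if any(g in pathway_genes for g in genes):
            pathway.add(snp)
        else:
            genomic.add(snp)
    return SnpPartition(
        pathway_snps=pathway,
        genomic_snps=genomic,
        dropped_intergenic=intergenic,
        assignments=genic_assignments,
    )
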