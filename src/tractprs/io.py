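"""Plain-text readers and writers for the pipeline's tables.

All genomic coordinates are 1-based with closed intervals; files declare
this in a leading comment line.  Tables are tab-separated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from tractprs import tracts as _tracts
from tractprs.phenotypes import TractMatrix
from tractprs.prs import GenotypeMatrix

_COORD_HEADER = "# coordinates: 1-based, closed intervals\n"

_SUMSTAT_MAP = {"odds_ratio": "OR", "se": "SE", "p": "P"}


def write_gene_map(gene_map: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        gene_map[["gene", "chrom", "tx_start", "tx_end"]].to_csv(
            fh, sep="\t", index=False
        )


def read_gene_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return df


def write_pathway_genes(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_pathway_genes(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_sumstats(variants: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "chrom", "pos", "ref", "alt", "effect_allele", "odds_ratio", "se", "p"]
    out = variants[cols].rename(columns=_SUMSTAT_MAP)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        out.to_csv(fh, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return df.rename(columns={v: k for k, v in _SUMSTAT_MAP.items()})


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.dosages.to_csv(path, sep="\t", index_label="subject", na_rep="NA")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject", na_values="NA")
    return GenotypeMatrix(df.astype(float))


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="subject")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject")


def write_phenotypes(matrices: dict[str, TractMatrix], path: str | Path) -> None:
    """Tidy table: subject, tract, hemisphere, measure, value."""
    frames = []
    for measure, tm in matrices.items():
        long = tm.values.stack(["tract", "hemisphere"], future_stack=True)
        long = long.rename("value").reset_index()
        long.columns = ["subject", "tract", "hemisphere", "value"]
        long.insert(3, "measure", measure)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> dict[str, TractMatrix]:
    tidy = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, TractMatrix] = {}
    for measure, grp in tidy.groupby("measure"):
        wide = grp.pivot(index="subject", columns=["tract", "hemisphere"], values="value")
        wide = wide[_tracts.tract_columns()]
        out[str(measure)] = TractMatrix(wide, str(measure))
    return out


def write_partition(partition, path_prefix: str | Path) -> None:
    """Two SNP-id list files plus the full assignment table."""
    prefix = Path(path_prefix)
    prefix.with_suffix(".pathway_snps.txt").write_text(
        "".join(f"{s}\n" for s in sorted(partition.pathway_snps))
    )
    prefix.with_suffix(".genomic_snps.txt").write_text(
        "".join(f"{s}\n" for s in sorted(partition.genomic_snps))
    )
    rows = []
    for snp in sorted(partition.pathway_snps):
        for g in partition.assignments[snp]:
            rows.append((snp, g, "pathway"))
    for snp in sorted(partition.genomic_snps):
        for g in partition.assignments[snp]:
            rows.append((snp, g, "genomic"))
    for snp in sorted(partition.dropped_intergenic):
        rows.append((snp, "", "intergenic"))
    pd.DataFrame(rows, columns=["id", "gene", "set"]).to_csv(
        prefix.with_suffix(".assignments.tsv"), sep="\t", index=False
    )


def write_scores(profiles: list, path: str | Path) -> None:
    """Tidy score table: subject, set, threshold, score."""
    frames = []
    for prof in profiles:
        long = prof.scores.stack().rename("score").reset_index()
        long.columns = ["subject", "threshold", "score"]
        long.insert(1, "set", prof.set_label)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
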