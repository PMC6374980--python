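"""End-to-end orchestration: simulate -> annotate -> score -> reduce ->
associate -> permute, with a run manifest and stage-level resume.

Each stage writes its outputs under ``out_dir`` and records row counts,
exclusion accounting and output file hashes in ``manifest.json``.  A rerun
with an identical configuration skips stages whose outputs already exist
under the same configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tractprs import io as tio
from tractprs import tracts as _tracts
from tractprs.annotate import annotate_snps, partition_by_pathway
from tractprs.association import (
    GENOMIC,
    PATHWAY,
    attach_fdr,
    fit_bilateral,
    fit_unilateral,
)
from tractprs.config import PipelineConfig
from tractprs.permutation import OutcomeSpec, run_permutation_analysis
from tractprs.phenotypes import (
    TractMatrix,
    category_scores,
    exclude_outliers,
    global_scores,
)
from tractprs.prs import clump, compute_prs
from tractprs.simulate import (
    simulate_cohort,
)

FAMILY_TRACTS = "tracts"
FAMILY_FACTORS = "factors"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    """Stateful runner; see :func:`run_all` for the one-shot entry point."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()

    def _load_manifest(self) -> dict:
        chash = _config_hash(self.config)
        if self.manifest_path.exists():
            m = json.loads(self.manifest_path.read_text())
            if m.get("config_hash") == chash:
                return m
        return {"config_hash": chash, "stages": {}}

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))

    def _stage_done(self, name: str, outputs: list[Path]) -> bool:
        rec = self.manifest["stages"].get(name)
        return rec is not None and all(p.exists() for p in outputs)

    def _record(self, name: str, outputs: list[Path], **info) -> None:
        self.manifest["stages"][name] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            **info,
        }
        self._save_manifest()

    # ------------------------------------------------------------------ stages

    def stage_simulate(self) -> None:
        cfg = self.config
        files = {
            n: self.out / f"{n}.tsv"
            for n in ("gene_map", "sumstats", "genotypes", "covariates", "phenotypes")
        }
        pathway_file = self.out / "pathway_genes.txt"
        outputs = [*files.values(), pathway_file]
        if cfg.simulation is None:
            src = Path(cfg.input_dir)
            for name, dst in files.items():
                if not (src / dst.name).exists():
                    raise FileNotFoundError(
                        f"stage simulate: missing input {src / dst.name}"
                    )
            return
        if self._stage_done("simulate", outputs):
            return
        cohort = simulate_cohort(
            cfg.simulation,
            flank=cfg.flank,
            prs_config=cfg.prs,
            planting_threshold=cfg.primary_threshold,
        )
        tio.write_gene_map(cohort.gene_map, files["gene_map"])
        tio.write_pathway_genes(cohort.pathway_genes, pathway_file)
        tio.write_sumstats(cohort.variants, files["sumstats"])
        tio.write_genotypes(cohort.genotypes, files["genotypes"])
        tio.write_covariates(cohort.covariates, files["covariates"])
        tio.write_phenotypes(cohort.tract_matrices, files["phenotypes"])
        self._record(
            "simulate",
            outputs,
            seed=cfg.simulation.seed,
            n_subjects=cfg.simulation.n_subjects,
            n_snps=cfg.simulation.n_snps,
        )

    def _data_dir(self) -> Path:
        return self.out if self.config.simulation is not None else Path(self.config.input_dir)

    def stage_annotate(self) -> None:
        data = self._data_dir()
        prefix = self.out / "partition"
        outputs = [
            prefix.with_suffix(".pathway_snps.txt"),
            prefix.with_suffix(".genomic_snps.txt"),
            prefix.with_suffix(".assignments.tsv"),
        ]
        if self._stage_done("annotate", outputs):
            return
        gene_map = tio.read_gene_map(data / "gene_map.tsv")
        pathway_genes = tio.read_pathway_genes(data / "pathway_genes.txt")
        variants = tio.read_sumstats(data / "sumstats.tsv")
        assignments = annotate_snps(variants, gene_map, flank=self.config.flank)
        partition = partition_by_pathway(
            assignments, set(pathway_genes), set(gene_map["gene"])
        )
        tio.write_partition(partition, prefix)
        self._record(
            "annotate",
            outputs,
            n_input=len(variants),
            n_pathway=len(partition.pathway_snps),
            n_genomic=len(partition.genomic_snps),
            n_intergenic_dropped=len(partition.dropped_intergenic),
        )

    def _load_partition(self):
        prefix = self.out / "partition"
        tbl = pd.read_csv(
            prefix.with_suffix(".assignments.tsv"), sep="\t", keep_default_na=False
        )
        from tractprs.annotate import SnpPartition

        assignments: dict[str, list[str]] = {}
        for snp, grp in tbl[tbl["set"] != "intergenic"].groupby("id"):
            assignments[str(snp)] = sorted(grp["gene"].astype(str))
        return SnpPartition(
            pathway_snps=set(tbl.loc[tbl["set"] == "pathway", "id"].astype(str)),
            genomic_snps=set(tbl.loc[tbl["set"] == "genomic", "id"].astype(str)),
            dropped_intergenic=set(
                tbl.loc[tbl["set"] == "intergenic", "id"].astype(str)
            ),
            assignments=assignments,
        )

    def stage_score(self) -> None:
        out = self.out / "scores.tsv"
        if self._stage_done("score", [out]):
            return
        data = self._data_dir()
        variants = tio.read_sumstats(data / "sumstats.tsv")
        genotypes = tio.read_genotypes(data / "genotypes.tsv")
        partition = self._load_partition()
        profiles = []
        counts = {}
        for label, snps in ((PATHWAY, partition.pathway_snps), (GENOMIC, partition.genomic_snps)):
            snp_set = set(snps)
            if self.config.prs.pruned:
                sub = variants[variants["id"].astype(str).isin(snp_set)]
                snp_set = clump(sub, genotypes, self.config.prs)
            prof = compute_prs(
                genotypes, variants, snp_set, self.config.prs, set_label=label
            )
            profiles.append(prof)
            counts[label] = prof.snp_counts
        tio.write_scores(profiles, out)
        self._record(
            "score",
            [out],
            pruned=self.config.prs.pruned,
            snp_counts={k: {str(t): n for t, n in v.items()} for k, v in counts.items()},
        )

    def stage_reduce(self) -> None:
        out = self.out / "factors.tsv"
        report = self.out / "variance_explained.tsv"
        kept_file = self.out / "kept_subjects.tsv"
        outputs = [out, report, kept_file]
        if self._stage_done("reduce", outputs):
            return
        data = self._data_dir()
        matrices = tio.read_phenotypes(data / "phenotypes.tsv")
        rows, frames, kept_rows = [], [], []
        excl_info = {}
        for measure in self.config.measures:
            tm = matrices[measure]
            kept, excluded = exclude_outliers(tm, self.config.outlier_k)
            excl_info[measure] = {
                "n_input": len(tm.values),
                "n_excluded": len(excluded),
                "n_kept": len(kept.values),
            }
            for s in kept.values.index:
                kept_rows.append((s, measure))
            g = global_scores(kept)
            entries = {"global": g}
            for cat in _tracts.CATEGORIES:
                entries[cat] = category_scores(kept, cat)
            for name, ls in entries.items():
                rows.append((measure, name, ls.pct_variance))
                long = ls.scores.rename("score").reset_index()
                long.columns = ["subject", "score"]
                long.insert(0, "factor", name)
                long.insert(0, "measure", measure)
                frames.append(long)
        pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
        pd.DataFrame(rows, columns=["measure", "factor", "pct_variance"]).to_csv(
            report, sep="\t", index=False
        )
        pd.DataFrame(kept_rows, columns=["subject", "measure"]).to_csv(
            kept_file, sep="\t", index=False
        )
        self._record("reduce", outputs, exclusions=excl_info)

    def _primary_scores(self) -> tuple[pd.Series, pd.Series]:
        scores = tio.read_scores(self.out / "scores.tsv")
        t = self.config.primary_threshold
        sub = scores[np.isclose(scores["threshold"], t)]
        path = sub[sub["set"] == PATHWAY].set_index("subject")["score"]
        gen = sub[sub["set"] == GENOMIC].set_index("subject")["score"]
        return path, gen

    def _kept_subjects(self, measure: str) -> list[str]:
        kept = pd.read_csv(self.out / "kept_subjects.tsv", sep="\t")
        return kept.loc[kept["measure"] == measure, "subject"].tolist()

    def stage_associate(self) -> None:
        out = self.out / "associations.tsv"
        if self._stage_done("associate", [out]):
            return
        data = self._data_dir()
        matrices = tio.read_phenotypes(data / "phenotypes.tsv")
        covariates = tio.read_covariates(data / "covariates.tsv")
        factors = pd.read_csv(self.out / "factors.tsv", sep="\t")
        prs_path, prs_gen = self._primary_scores()
        rows = []
        for measure in self.config.measures:
            keep = self._kept_subjects(measure)
            tm = TractMatrix(matrices[measure].values.loc[keep], measure)
            cov = covariates.loc[keep]
            # 15 individual tracts
            for t in _tracts.TRACTS:
                if t.bilateral:
                    res = fit_bilateral(
                        tm.values[(t.name, _tracts.LEFT)],
                        tm.values[(t.name, _tracts.RIGHT)],
                        prs_path,
                        prs_gen,
                        cov,
                    )
                else:
                    res = fit_unilateral(
                        tm.values[(t.name, _tracts.MIDLINE)], prs_path, prs_gen, cov
                    )
                for term in (PATHWAY, GENOMIC):
                    r = res[term]
                    rows.append(
                        (measure, FAMILY_TRACTS, t.name, term, r.beta, r.se, r.t, r.p, r.r2_pct, r.n)
                    )
            # global + category factors
            fsub = factors[factors["measure"] == measure]
            for fname in ("global", *_tracts.CATEGORIES):
                sc = fsub[fsub["factor"] == fname].set_index("subject")["score"]
                res = fit_unilateral(sc, prs_path, prs_gen, covariates.loc[sc.index])
                for term in (PATHWAY, GENOMIC):
                    r = res[term]
                    rows.append(
                        (measure, FAMILY_FACTORS, fname, term, r.beta, r.se, r.t, r.p, r.r2_pct, r.n)
                    )
        results = pd.DataFrame(
            rows,
            columns=["measure", "family", "outcome", "term", "beta", "se", "t", "p", "r2_pct", "n"],
        )
        results = attach_fdr(results)
        results.to_csv(out, sep="\t", index=False, float_format="%.6g")
        self._make_figures(results)
        self._record("associate", [out], n_models=len(results) // 2)

    def _make_figures(self, results: pd.DataFrame) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for (measure, family), grp in results.groupby(["measure", "family"]):
            fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharey=True)
            for ax, term in zip(axes, (PATHWAY, GENOMIC)):
                sub = grp[grp["term"] == term]
                y = np.arange(len(sub))
                ax.errorbar(sub["beta"], y, xerr=sub["se"], fmt="o", capsize=3)
                ax.axvline(0.0, color="grey", lw=0.8)
                ax.set_yticks(y)
                ax.set_yticklabels(sub["outcome"])
                ax.set_xlabel("standardized beta")
                ax.set_title(f"{term} PRS")
            fig.suptitle(f"{measure} {family}")
            fig.tight_layout()
            fig.savefig(self.out / f"forest_{measure}_{family}.png", dpi=100)
            plt.close(fig)

    def stage_permute(self) -> None:
        out = self.out / "permutation.tsv"
        if self._stage_done("permute", [out]):
            return
        data = self._data_dir()
        results = pd.read_csv(self.out / "associations.tsv", sep="\t")
        sig = results[(results["term"] == PATHWAY) & (results["p_fdr"] < 0.05)]
        if sig.empty:
            pd.DataFrame(
                columns=["measure", "outcome", "observed_beta", "observed_t", "p_emp"]
            ).to_csv(out, sep="\t", index=False)
            self._record("permute", [out], n_outcomes=0, note="no significant pathway outcomes")
            return
        matrices = tio.read_phenotypes(data / "phenotypes.tsv")
        covariates = tio.read_covariates(data / "covariates.tsv")
        genotypes = tio.read_genotypes(data / "genotypes.tsv")
        variants = tio.read_sumstats(data / "sumstats.tsv")
        partition = self._load_partition()
        factors = pd.read_csv(self.out / "factors.tsv", sep="\t")
        _, prs_gen = self._primary_scores()
        rows = []
        null_frames = []
        for measure, grp in sig.groupby("measure"):
            keep = self._kept_subjects(measure)
            tm = matrices[measure]
            specs = []
            for outcome in grp["outcome"]:
                if outcome in _tracts.TRACT_BY_NAME:
                    t = _tracts.TRACT_BY_NAME[outcome]
                    if t.bilateral:
                        specs.append(
                            OutcomeSpec(
                                outcome,
                                (
                                    tm.values.loc[keep, (t.name, _tracts.LEFT)],
                                    tm.values.loc[keep, (t.name, _tracts.RIGHT)],
                                ),
                            )
                        )
                    else:
                        specs.append(
                            OutcomeSpec(outcome, tm.values.loc[keep, (t.name, _tracts.MIDLINE)])
                        )
                else:
                    fsub = factors[
                        (factors["measure"] == measure) & (factors["factor"] == outcome)
                    ].set_index("subject")["score"]
                    specs.append(OutcomeSpec(outcome, fsub))
            nulls = run_permutation_analysis(
                genotypes,
                variants,
                partition,
                specs,
                covariates,
                prs_gen,
                n_perm=self.config.n_perm,
                seed=self.config.seed,
                threshold=self.config.primary_threshold,
            )
            for name, null in nulls.items():
                rows.append((measure, name, null.observed_beta, null.observed, null.p_emp))
                null_frames.append(
                    pd.DataFrame(
                        {"measure": measure, "outcome": name, "stat": null.stats}
                    )
                )
        pd.DataFrame(
            rows, columns=["measure", "outcome", "observed_beta", "observed_t", "p_emp"]
        ).to_csv(out, sep="\t", index=False, float_format="%.6g")
        pd.concat(null_frames, ignore_index=True).to_csv(
            self.out / "permutation_null_stats.tsv", sep="\t", index=False, float_format="%.6g"
        )
        self._record("permute", [out], n_outcomes=len(rows), n_perm=self.config.n_perm)

    def run_all(self) -> dict:
        for stage in (
            self.stage_simulate,
            self.stage_annotate,
            self.stage_score,
            self.stage_reduce,
            self.stage_associate,
            self.stage_permute,
        ):
            name = stage.__name__.removeprefix("stage_")
            try:
                stage()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return self.manifest


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest."""
    return Pipeline(config).run_all()
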