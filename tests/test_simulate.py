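"""Synthetic cohort generator: determinism, LD structure, GWAS calibration,
factor-structured phenotypes and planted effects."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from tractprs.config import SimulationConfig
from tractprs.simulate import (
    simulate_cohort,
    simulate_covariates,
    simulate_gene_map,
    simulate_genotypes,
    simulate_gwas_sumstats,
    simulate_phenotypes,
)


def _cfg(**kw):
    base = dict(
        n_subjects=300, n_snps=200, n_genes=40, pathway_n_genes=8,
        n_chromosomes=4, seed=1, planted_beta={},
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGeneMap:
    def test_determinism(self):
        a = simulate_gene_map(_cfg())
        b = simulate_gene_map(_cfg())
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_pathway_equals_full_list_when_sizes_match(self):
        gm, pathway = simulate_gene_map(_cfg(n_genes=43, pathway_n_genes=43))
        assert sorted(pathway) == sorted(gm["gene"])

    def test_pathway_names_in_map_exactly_once(self):
        gm, pathway = simulate_gene_map(_cfg())
        counts = gm["gene"].value_counts()
        for g in pathway:
            assert counts[g] == 1

    def test_no_overlaps_and_wide_gaps(self):
        gm, _ = simulate_gene_map(_cfg())
        wide = 0
        for _, grp in gm.groupby("chrom"):
            grp = grp.sort_values("tx_start")
            starts, ends = grp["tx_start"].to_numpy(), grp["tx_end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()  # non-overlapping
            wide += int(np.sum(starts[1:] - ends[:-1] > 2 * 20_000))
            wide += int(starts[0] > 2 * 20_000)
        assert wide >= len(gm) // 2

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            simulate_gene_map(_cfg(pathway_n_genes=100))


class TestGenotypes:
    def test_dosage_bounds_and_determinism(self):
        cfg = _cfg()
        gm, _ = simulate_gene_map(cfg)
        g1, v1 = simulate_genotypes(cfg, gm)
        g2, v2 = simulate_genotypes(cfg, gm)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(v1, v2)
        assert set(np.unique(g1.dosages.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_no_ld_limit(self):
        """ld_rho=0: allele frequency matches MAF and adjacent r2 is tiny."""
        cfg = _cfg(n_subjects=5000, n_snps=60, ld_rho=0.0, maf_range=(0.3, 0.3))
        gm, _ = simulate_gene_map(cfg)
        geno, variants = simulate_genotypes(cfg, gm)
        dose = geno.dosages.to_numpy()
        freq = dose.mean(axis=0) / 2
        assert np.all(np.abs(freq - 0.3) < 0.02)
        r2 = [
            np.corrcoef(dose[:, j], dose[:, j + 1])[0, 1] ** 2
            for j in range(dose.shape[1] - 1)
        ]
        assert np.mean(r2) < 0.01

    def test_block_size_one_kills_ld(self):
        cfg = _cfg(n_subjects=3000, n_snps=50, ld_block_size=1, ld_rho=0.9)
        gm, _ = simulate_gene_map(cfg)
        geno, _ = simulate_genotypes(cfg, gm)
        dose = geno.dosages.to_numpy()
        r2 = [
            np.corrcoef(dose[:, j], dose[:, j + 1])[0, 1] ** 2
            for j in range(dose.shape[1] - 1)
        ]
        assert np.mean(r2) < 0.01

    def test_within_block_exceeds_cross_block(self):
        cfg = _cfg(n_subjects=5000, n_snps=100, ld_block_size=5, ld_rho=0.9,
                   n_chromosomes=1)
        gm, _ = simulate_gene_map(cfg)
        geno, variants = simulate_genotypes(cfg, gm)
        dose = geno.dosages.to_numpy()
        within, cross = [], []
        for j in range(dose.shape[1] - 1):
            r2 = np.corrcoef(dose[:, j], dose[:, j + 1])[0, 1] ** 2
            (cross if (j + 1) % 5 == 0 else within).append(r2)
        assert np.mean(within) > np.mean(cross)
        # haplotype copying gives adjacent dosage correlation ~ ld_rho
        assert np.mean(within) == pytest.approx(0.81, abs=0.08)

    def test_bad_maf_range(self):
        with pytest.raises(ValueError):
            _cfg(maf_range=(0.0, 0.3)).validate()
        with pytest.raises(ValueError):
            _cfg(maf_range=(0.1, 0.6)).validate()


class TestSumstats:
    def test_null_pvalues_uniform(self):
        """Zero true effects -> p values uniform on (0,1) by KS test."""
        cfg = _cfg(n_snps=5000, n_genes=100, pathway_effect_sd=0.0,
                   genomic_effect_sd=0.0)
        gm, _ = simulate_gene_map(cfg)
        _, variants = simulate_genotypes(cfg, gm)
        ss = simulate_gwas_sumstats(cfg, variants, set())
        assert sps.kstest(ss["p"], "uniform").pvalue > 0.01

    def test_internal_consistency(self):
        """|log(OR)| / SE reconstructs the p value to 1e-10."""
        cfg = _cfg()
        gm, _ = simulate_gene_map(cfg)
        _, variants = simulate_genotypes(cfg, gm)
        ss = simulate_gwas_sumstats(cfg, variants, set(variants["id"][:50]))
        z = np.log(ss["odds_ratio"]) / ss["se"]
        p = np.clip(2 * sps.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
        assert np.allclose(p, ss["p"], atol=1e-10)

    def test_noiseless_limit(self):
        """gwas_n -> infinity: observed log-odds equal the true effects."""
        cfg = _cfg(gwas_n=10**18)
        gm, _ = simulate_gene_map(cfg)
        _, variants = simulate_genotypes(cfg, gm)
        ss = simulate_gwas_sumstats(cfg, variants, set())
        assert np.allclose(np.log(ss["odds_ratio"]), ss["true_logodds"], atol=1e-4)

    def test_pathway_enrichment(self):
        cfg = _cfg(n_snps=2000, n_genes=100, pathway_effect_sd=0.01,
                   genomic_effect_sd=0.001)
        gm, _ = simulate_gene_map(cfg)
        _, variants = simulate_genotypes(cfg, gm)
        members = set(variants["id"][:1000])
        ss = simulate_gwas_sumstats(cfg, variants, members)
        in_path = ss["id"].isin(members)
        assert ss.loc[in_path, "true_logodds"].abs().mean() > \
            ss.loc[~in_path, "true_logodds"].abs().mean()


class TestPhenotypes:
    def _prs(self, n, seed):
        rng = np.random.default_rng(seed)
        idx = [f"S{i:06d}" for i in range(1, n + 1)]
        z = rng.normal(size=n)
        return pd.Series((z - z.mean()) / z.std(), index=idx)

    def test_null_correlations(self):
        """No planted effects: tract-PRS correlations stay near zero."""
        cfg = _cfg(n_subjects=4000)
        prs = self._prs(4000, 0)
        mats, _ = simulate_phenotypes(cfg, prs, self._prs(4000, 1))
        bound = 3 * 2 / np.sqrt(4000)
        for measure, tm in mats.items():
            cors = tm.values.apply(lambda c: np.corrcoef(c, prs)[0, 1])
            assert np.all(np.abs(cors.to_numpy()) < bound)

    def test_single_factor_degeneracy(self):
        cfg = _cfg(tract_loading_global=1.0, tract_loading_category=0.0,
                   tract_noise_sd=0.0, hemisphere_rho=1.0)
        prs = self._prs(300, 0)
        mats, _ = simulate_phenotypes(cfg, prs, self._prs(300, 1))
        corr = np.corrcoef(mats["FA"].values.to_numpy().T)
        assert np.allclose(corr, 1.0, atol=1e-10)

    def test_planted_effect_recovered_by_regression(self):
        cfg = _cfg(
            n_subjects=5000,
            planted_beta={("forceps major", "FA"): 0.1},
        )
        prs = self._prs(5000, 3)
        mats, _ = simulate_phenotypes(cfg, prs, self._prs(5000, 4))
        y = mats["FA"].values[("forceps major", "")]
        y = (y - y.mean()) / y.std()
        beta = np.polyfit(prs.to_numpy(), y.to_numpy(), 1)[0]
        # planted beta on the standardized outcome scale
        total_sd = np.sqrt(
            cfg.tract_loading_global**2 + cfg.tract_loading_category**2
            + 0.1**2 + cfg.tract_noise_sd**2
        )
        assert beta == pytest.approx(0.1 / total_sd, abs=0.04)

    def test_unknown_tract_rejected(self):
        with pytest.raises(ValueError, match="unknown tract"):
            _cfg(planted_beta={("no such tract", "FA"): 0.1}).validate()

    def test_hemisphere_correlation(self):
        cfg = _cfg(n_subjects=5000, tract_loading_global=0.0,
                   tract_loading_category=0.0, hemisphere_rho=0.7)
        prs = self._prs(5000, 5)
        mats, _ = simulate_phenotypes(cfg, prs, self._prs(5000, 6))
        tm = mats["FA"]
        r = np.corrcoef(
            tm.values[("superior longitudinal fasciculus", "left")],
            tm.values[("superior longitudinal fasciculus", "right")],
        )[0, 1]
        # with no shared signal, left/right correlation equals hemisphere_rho
        assert r == pytest.approx(0.7, abs=0.05)


class TestCovariatesAndCohort:
    def test_covariate_structure(self):
        cov = simulate_covariates(_cfg(n_subjects=500))
        pcs = cov[[f"pc{i}" for i in range(1, 16)]].to_numpy()
        gram = pcs.T @ pcs / len(pcs)
        assert np.allclose(gram, np.eye(15), atol=1e-8)  # orthonormal PCs
        assert set(np.unique(cov["sex"])) <= {0.0, 1.0}
        assert cov["age"].between(45, 79).all()

    def test_cohort_determinism(self):
        c1 = simulate_cohort(_cfg(seed=42))
        c2 = simulate_cohort(_cfg(seed=42))
        pd.testing.assert_frame_equal(c1.variants, c2.variants)
        pd.testing.assert_frame_equal(c1.genotypes.dosages, c2.genotypes.dosages)
        for m in ("FA", "MD"):
            pd.testing.assert_frame_equal(
                c1.tract_matrices[m].values, c2.tract_matrices[m].values
            )
        assert c1.partition.pathway_snps == c2.partition.pathway_snps

    def test_all_values_finite(self, small_cohort):
        for tm in small_cohort.tract_matrices.values():
            assert np.isfinite(tm.values.to_numpy()).all()
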