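"""Joint PRS association models and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tractprs.association import (
    attach_fdr,
    build_design,
    fdr_adjust,
    fit_bilateral,
    fit_unilateral,
)


def _covariates(rng, n):
    idx = [f"S{i}" for i in range(n)]
    cov = pd.DataFrame(index=idx)
    cov["age"] = rng.uniform(45, 79, n)
    cov["sex"] = rng.integers(0, 2, n).astype(float)
    for i in range(1, 16):
        cov[f"pc{i}"] = rng.normal(size=n)
    for a in ("x", "y", "z"):
        cov[f"head_{a}"] = rng.normal(size=n)
    cov["array"] = (rng.random(n) < 0.1).astype(float)
    return cov


def _std_series(rng, n, idx=None):
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std()
    return pd.Series(z, index=idx if idx is not None else [f"S{i}" for i in range(n)])


def _bh_oracle(p):
    """Literal step-up definition: adj_i = min over p_(j) >= p_i of p_(j)*m/rank(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for i in range(m):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestFdrAdjust:
    # uncorrected p values of the 15-tract pathway-PRS FA family as printed
    FA_PATHWAY_P = [.020, .435, .046, .043, .002, .081, .057, .205, .622,
                    .759, .863, .400, .193, .135, .140]

    def test_fifteen_tract_family_smallest_value(self):
        """Smallest adjusted value of the 15-tract pathway family is 0.030."""
        adj = fdr_adjust(self.FA_PATHWAY_P)
        assert round(min(adj), 3) == 0.030
        assert round(adj[self.FA_PATHWAY_P.index(0.002)], 3) == 0.030

    def test_four_value_family(self):
        """Global + three category factors: 0.028 adjusts to 0.056 at m=4."""
        adj = fdr_adjust([0.028, 0.006, 0.138, 0.366])
        assert round(adj[0], 3) == 0.056

    def test_single_p_identity(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_largest_p_unchanged(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=9)
        adj = fdr_adjust(p)
        assert adj[np.argmax(p)] == pytest.approx(min(1.0, p.max()))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        p = rng.uniform(size=8)
        assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_monotone_and_dominating(self, p):
        adj = fdr_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)  # p_fdr >= p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in p

    def test_idempotent_on_adjusted(self):
        rng = np.random.default_rng(1)
        adj = fdr_adjust(rng.uniform(size=10))
        # re-adjusting an already step-up-adjusted (hence monotone) family at
        # the same ranks cannot push values past 1
        assert np.all(fdr_adjust(adj) <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])

    def test_attach_fdr_families(self):
        df = pd.DataFrame(
            {
                "measure": ["FA"] * 4 + ["MD"] * 4,
                "term": ["pathway"] * 8,
                "family": ["factors"] * 8,
                "p": [0.028, 0.006, 0.138, 0.366, 0.016, 0.058, 0.005, 0.077],
            }
        )
        out = attach_fdr(df)
        assert round(out.loc[0, "p_fdr"], 3) == 0.056
        assert round(out.loc[6, "p_fdr"], 3) == 0.020  # MD family adjusted separately


class TestFitUnilateral:
    def test_parameter_recovery(self):
        """Planted 0.1 effect recovered; genomic term unbiased at zero."""
        rng = np.random.default_rng(10)
        n = 5000
        cov = _covariates(rng, n)
        prs_p = _std_series(rng, n, cov.index)
        prs_g = _std_series(rng, n, cov.index)
        y = 0.1 * prs_p + rng.normal(size=n)
        res = fit_unilateral(y, prs_p, prs_g, cov)
        assert res["pathway"].beta == pytest.approx(0.1, abs=0.04)
        assert res["genomic"].beta == pytest.approx(0.0, abs=0.04)
        assert res["pathway"].t == pytest.approx(
            res["pathway"].beta / res["pathway"].se, abs=1e-10
        )

    def test_outcome_equal_to_covariate(self):
        rng = np.random.default_rng(11)
        n = 400
        cov = _covariates(rng, n)
        res = fit_unilateral(cov["pc3"], _std_series(rng, n, cov.index),
                             _std_series(rng, n, cov.index), cov)
        assert abs(res["pathway"].beta) < 1e-8
        assert abs(res["genomic"].beta) < 1e-8

    def test_collinear_design_reported(self):
        rng = np.random.default_rng(12)
        n = 200
        cov = _covariates(rng, n)
        cov["dup"] = cov["age"] * 2.0
        y = _std_series(rng, n, cov.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_unilateral(y, _std_series(rng, n, cov.index),
                           _std_series(rng, n, cov.index), cov)

    def test_joint_matches_single_when_orthogonal(self):
        """With PRSs orthogonalized in sample, the joint estimate matches the
        single-predictor model."""
        rng = np.random.default_rng(13)
        n = 2000
        cov = _covariates(rng, n)
        a = _std_series(rng, n, cov.index)
        # orthogonalize b against a AND the covariate design so the joint
        # model's normal equations decouple exactly
        import statsmodels.api as sm

        nuisance = sm.add_constant(
            pd.concat([a.rename("a"), build_design(cov)], axis=1), prepend=True
        ).to_numpy()
        q, _ = np.linalg.qr(nuisance)
        b_raw = rng.normal(size=n)
        b_raw = b_raw - q @ (q.T @ b_raw)
        b = pd.Series(b_raw / b_raw.std(), index=cov.index)
        y = 0.05 * a + rng.normal(size=n)
        joint = fit_unilateral(y, a, b, cov)
        zero = pd.Series(np.zeros(n), index=cov.index)
        # single-PRS model: drop the other term by fitting y ~ a + covariates
        import statsmodels.api as sm

        X = sm.add_constant(
            pd.concat([a.rename("a"), build_design(cov)], axis=1), prepend=True
        )
        ys = (y - y.mean()) / y.to_numpy().std()  # ddof=0, as the model uses
        single = sm.OLS(ys.to_numpy(), X).fit()
        assert joint["pathway"].beta == pytest.approx(single.params["a"], abs=1e-6)

    def test_r2_increment_matches_partial_correlation(self):
        """r2_pct ~ 100 * partial correlation^2 for orthogonal designs."""
        rng = np.random.default_rng(14)
        n = 20_000
        cov = _covariates(rng, n)
        prs_p = _std_series(rng, n, cov.index)
        prs_g = _std_series(rng, n, cov.index)
        y = 0.1 * prs_p + rng.normal(size=n)
        res = fit_unilateral(y, prs_p, prs_g, cov, r2_mode="raw")
        expected = 100 * (0.1**2) / (0.1**2 + 1.0)
        assert res["pathway"].r2_pct == pytest.approx(expected, rel=0.25)

    def test_null_pvalues_uniform(self):
        """Null calibration: with no effect, both PRS p values are uniform."""
        import scipy.stats as sps

        rng = np.random.default_rng(15)
        n = 300
        pvals_p, pvals_g = [], []
        for _ in range(200):
            cov = _covariates(rng, n)
            res = fit_unilateral(
                _std_series(rng, n, cov.index),
                _std_series(rng, n, cov.index),
                _std_series(rng, n, cov.index),
                cov,
            )
            pvals_p.append(res["pathway"].p)
            pvals_g.append(res["genomic"].p)
        assert sps.kstest(pvals_p, "uniform").pvalue > 0.01
        assert sps.kstest(pvals_g, "uniform").pvalue > 0.01


class TestFitBilateral:
    def test_degenerate_equals_unilateral(self):
        """Identical hemispheres collapse to the ordinary linear model."""
        rng = np.random.default_rng(20)
        n = 300
        cov = _covariates(rng, n)
        prs_p = _std_series(rng, n, cov.index)
        prs_g = _std_series(rng, n, cov.index)
        y = 0.05 * prs_p + pd.Series(rng.normal(size=n), index=cov.index)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bil = fit_bilateral(y, y, prs_p, prs_g, cov)
        uni = fit_unilateral(y, prs_p, prs_g, cov)
        assert bil["pathway"].beta == pytest.approx(uni["pathway"].beta, abs=1e-6)
        assert bil["genomic"].beta == pytest.approx(uni["genomic"].beta, abs=1e-6)

    def test_hemisphere_shift_invariance(self):
        """Adding +0.3 to all right values moves only the hemisphere term."""
        rng = np.random.default_rng(21)
        n = 500
        cov = _covariates(rng, n)
        prs_p = _std_series(rng, n, cov.index)
        prs_g = _std_series(rng, n, cov.index)
        subj = 0.1 * prs_p + pd.Series(rng.normal(size=n), index=cov.index)
        left = subj + rng.normal(0, 0.5, n)
        right = subj + rng.normal(0, 0.5, n)
        base = fit_bilateral(left, right, prs_p, prs_g, cov)
        shifted = fit_bilateral(left, right + 0.3, prs_p, prs_g, cov)
        # outcome restandardization rescales betas by the stacked SD ratio
        scale = np.std(np.concatenate([left, right + 0.3])) / np.std(
            np.concatenate([left, right])
        )
        assert shifted["pathway"].beta * scale == pytest.approx(
            base["pathway"].beta, abs=1e-6
        )
        assert shifted["hemisphere"].beta * np.std(
            np.concatenate([left, right + 0.3])
        ) == pytest.approx(0.3 + base["hemisphere"].beta * np.std(
            np.concatenate([left, right])), abs=0.01)

    def test_subject_level_recovery(self):
        """Planted subject-level effect 0.1 with hemisphere noise sd 0.5."""
        rng = np.random.default_rng(22)
        n = 2000
        cov = _covariates(rng, n)
        prs_p = _std_series(rng, n, cov.index)
        prs_g = _std_series(rng, n, cov.index)
        subj = 0.1 * prs_p + pd.Series(rng.normal(size=n), index=cov.index)
        left = subj + rng.normal(0, 0.5, n)
        right = subj + rng.normal(0, 0.5, n)
        res = fit_bilateral(left, right, prs_p, prs_g, cov)
        # beta is on the standardized stacked-outcome scale
        total_sd = np.sqrt(0.1**2 + 1.0 + 0.25)
        assert res["pathway"].beta == pytest.approx(0.1 / total_sd, abs=0.05)
        assert res["genomic"].beta == pytest.approx(0.0, abs=0.05)

    def test_mismatched_subjects_rejected(self):
        rng = np.random.default_rng(23)
        cov = _covariates(rng, 50)
        y = _std_series(rng, 50, cov.index)
        other = y.copy()
        other.index = [f"T{i}" for i in range(50)]
        with pytest.raises(ValueError, match="same subjects"):
            fit_bilateral(y, other, y, y, cov)
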