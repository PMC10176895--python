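"""Per-CpG binomial GLM, q-values, DMC calling and set comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

import methylseq_dm as md
from methylseq_dm.dmc import build_design


def _two_group_X(n_per):
    return np.column_stack([np.ones(2 * n_per),
                            np.repeat([0.0, 1.0], n_per)])


class TestFitSiteGlm:
    def test_symmetric_data_gives_null(self):
        X = _two_group_X(3)
        m = np.full(6, 50)
        t = np.full(6, 100)
        coef, se, z, p, ok = md.fit_site_glm(m, t, X)
        assert ok
        assert coef == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_two_group(self):
        """3x(50/100) vs 3x(80/100): coef = logit(.8)-logit(.5), Fisher info
        gives z = coef / sqrt(1/75 + 1/48)."""
        X = _two_group_X(3)
        m = np.array([50, 50, 50, 80, 80, 80])
        t = np.full(6, 100)
        coef, se, z, p, ok = md.fit_site_glm(m, t, X)
        assert coef == pytest.approx(np.log(0.8 / 0.2) - 0.0, abs=1e-8)
        assert z == pytest.approx(1.3862944 / np.sqrt(1 / 75 + 1 / 48), rel=1e-5)

    def test_label_symmetry(self):
        X = _two_group_X(4)
        rng = np.random.default_rng(3)
        t = rng.integers(20, 80, 8)
        m = rng.binomial(t, 0.4)
        c1, _, _, p1, _ = md.fit_site_glm(m, t, X)
        c2, _, _, p2, _ = md.fit_site_glm(t - m, t, X)
        assert c2 == pytest.approx(-c1, rel=1e-8)
        assert p2 == pytest.approx(p1, rel=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_statsmodels(self, seed):
        """Independent maximum-likelihood oracle: statsmodels binomial GLM."""
        rng = np.random.default_rng(seed)
        n = 16
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                             rng.normal(size=n)])
        if np.ptp(X[:, 1]) == 0:
            X[0, 1] = 1 - X[0, 1]
        t = rng.integers(15, 120, n)
        m = rng.binomial(t, 0.3 + 0.2 * X[:, 1])
        coef, se, z, p, ok = md.fit_site_glm(m, t, X)
        assert ok
        fit = sm.GLM(np.column_stack([m, t - m]), X,
                     family=sm.families.Binomial()).fit()
        assert coef == pytest.approx(fit.params[1], abs=1e-6)
        assert se == pytest.approx(fit.bse[1], rel=1e-4)

    def test_complete_separation_flagged(self):
        X = _two_group_X(3)
        m = np.array([0, 0, 0, 50, 50, 50])
        t = np.full(6, 50)
        *_, ok = md.fit_site_glm(m, t, X)
        assert not ok


class TestQvalues:
    def test_fixed_pi0_equals_bh(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(5, 400))
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(md.qvalues(p, "fixed_one"), bh, rtol=1e-12, atol=0)

    def test_worked_example(self):
        q = md.qvalues(np.array([0.01, 0.02, 0.03, 0.04]), "fixed_one")
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_rank_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.beta(0.3, 1.0, 2000)
        q = md.qvalues(p, "smoother")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert q.max() <= 1.0 and q.min() >= 0.0

    def test_pi0_near_one_under_uniform_null(self):
        rng = np.random.default_rng(2)
        p = rng.random(10_000)
        q = md.qvalues(p, "smoother")
        bh = multipletests(p, method="fdr_bh")[1]
        # pi0-hat = q / BH ratio; must be within 0.05 of 1 under the null
        ratio = q[p < 0.5] / bh[p < 0.5]
        assert abs(ratio.mean() - 1) < 0.05

    def test_empty_input(self):
        assert md.qvalues(np.array([])).size == 0


class TestMethylationDifference:
    def test_worked_example(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [0]})
        t = np.full((1, 4), 10)
        m = np.array([[6, 8, 5, 5]])
        mat = md.MethylomeMatrix(sites, list("abcd"), m, t)
        d = md.methylation_difference(mat, ["a", "b"], ["c", "d"])
        assert d[0] == pytest.approx(0.20)

    def test_matches_brute_force(self, filtered, small_cohort):
        sheet = small_cohort["sheet"]
        case = list(sheet[sheet.group == "case"]["sample_id"])
        ctrl = list(sheet[sheet.group == "control"]["sample_id"])
        d = md.methylation_difference(filtered, case, ctrl)
        beta = filtered.beta()
        for i in [0, 5, 100, 500]:
            bc = [beta[i, filtered.samples.index(s)] for s in case]
            bg = [beta[i, filtered.samples.index(s)] for s in ctrl]
            exp = np.nanmean(bc) - np.nanmean(bg)
            assert d[i] == pytest.approx(exp, nan_ok=True)


class TestCallDmcs:
    def test_recovery_and_direction(self, small_cohort, filtered):
        props = md.deconvolve(filtered, small_cohort["panel"])
        res = md.call_dmcs(filtered, small_cohort["sheet"],
                           md.DesignSpec(covariates=("sex", "cells")),
                           proportions=props)
        truth = small_cohort["truth"]
        # sites planted with a 'both'-scope effect and retained after filtering
        keys = set(zip(filtered.sites.chrom, filtered.sites.pos))
        mat = small_cohort["matrix"]
        planted = {}
        for site, (em, ef) in truth.true_dmc_sites.items():
            k = (mat.sites.chrom[site], mat.sites.pos[site])
            if em == ef and em != 0 and k in keys:
                planted[k] = em
        called = set(zip(res.dmcs.chrom, res.dmcs.pos))
        hit = called & set(planted)
        assert len(hit) / len(planted) >= 0.6  # n=10+10 toy cohort
        cd = res.dmcs.set_index(["chrom", "pos"])
        signs = [np.sign(cd.loc[k, "meth_diff"]) == np.sign(planted[k]) for k in hit]
        assert np.mean(signs) >= 0.95

    def test_opposite_scope_seen_in_sex_stratified_calls(self, small_cohort, filtered):
        """A site planted with opposite-direction sex effects shows opposite
        meth_diff signs in the male-only and female-only analyses."""
        sheet = small_cohort["sheet"]
        truth = small_cohort["truth"]
        mat = small_cohort["matrix"]
        res_m = md.call_dmcs(filtered, sheet, md.DesignSpec(
            covariates=(), sample_subset="males"), pi0_mode="fixed_one")
        res_f = md.call_dmcs(filtered, sheet, md.DesignSpec(
            covariates=(), sample_subset="females"), pi0_mode="fixed_one")
        fm = res_m.results.set_index(["chrom", "pos"])
        ff = res_f.results.set_index(["chrom", "pos"])
        checked = 0
        for site, (em, ef) in truth.true_dmc_sites.items():
            if em * ef < 0:
                k = (mat.sites.chrom[site], mat.sites.pos[site])
                if k in fm.index and k in ff.index:
                    dm, df_ = fm.loc[k, "meth_diff"], ff.loc[k, "meth_diff"]
                    if abs(dm) > 0.05 and abs(df_) > 0.05:
                        assert dm * df_ < 0
                        checked += 1
        assert checked >= 3

    def test_sites_with_one_empty_group_skipped(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [0]})
        mat = md.MethylomeMatrix(sites, list("abcd"), np.array([[5, 5, 5, 5]]),
                                 np.full((1, 4), 10),
                                 np.array([[False, False, True, True]]))
        sheet = pd.DataFrame({"sample_id": list("abcd"),
                              "group": ["control", "control", "case", "case"],
                              "sex": ["M", "F", "M", "F"]})
        res = md.call_dmcs(mat, sheet, md.DesignSpec(covariates=()))
        assert not res.results["tested"].iloc[0]


class TestCompareDmcSets:
    def test_overlap_counts(self):
        a = pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3], "meth_diff": [.1, .1, .1]})
        b = pd.DataFrame({"chrom": "chr1", "pos": [2, 3, 4], "meth_diff": [.1, .1, .1]})
        r = md.compare_dmc_sets(a, b)
        assert (r["n_shared"], r["n_a_only"], r["n_b_only"]) == (2, 1, 1)
        assert r["frac_a_shared"] == pytest.approx(2 / 3)

    def test_direction_and_similarity_rule(self):
        a = pd.DataFrame({"chrom": "chr1", "pos": [1], "meth_diff": [0.08]})
        b = pd.DataFrame({"chrom": "chr1", "pos": [1], "meth_diff": [-0.03]})
        r = md.compare_dmc_sets(a, b, tolerance=0.05)
        assert r["n_opposite_direction"] == 1
        assert r["n_similar_magnitude"] == 0

    def test_disjoint_sets(self):
        a = pd.DataFrame({"chrom": "chr1", "pos": [1], "meth_diff": [0.1]})
        b = pd.DataFrame({"chrom": "chr2", "pos": [1], "meth_diff": [0.1]})
        assert md.compare_dmc_sets(a, b)["n_shared"] == 0


class TestBuildDesign:
    def test_sex_dropped_when_stratified(self, small_cohort):
        _, X, names = build_design(small_cohort["sheet"],
                                   md.DesignSpec(covariates=("sex",),
                                                 sample_subset="males"))
        assert "sex_M" not in names

    def test_constant_covariate_rejected(self, small_cohort):
        sheet = small_cohort["sheet"].assign(batch=1.0)
        with pytest.raises(ValueError, match="constant"):
            build_design(sheet, md.DesignSpec(covariates=("batch",)))

    def test_orthogonal_covariate_barely_moves_contrast(self):
        """Balanced sex with no sex effect: adding it changes the group
        coefficient only within simulation noise."""
        cfg = md.SimulationConfig(n_cpgs=300, n_control=20, n_case=20, seed=6,
                                  planted_effects=[md.PlantedEffect(0, 1.0)],
                                  missing_rate=0.0, markers_per_type=5)
        panel = md.simulate_reference_panel(cfg)
        mat, sheet, _ = md.simulate_cohort(cfg, panel)
        r0 = md.call_dmcs(mat, sheet, md.DesignSpec(covariates=()))
        r1 = md.call_dmcs(mat, sheet, md.DesignSpec(covariates=("sex",)))
        c0 = r0.results.loc[0, "coef"]
        c1 = r1.results.loc[0, "coef"]
        assert c1 == pytest.approx(c0, abs=0.15)
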