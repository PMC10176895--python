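"""Contingency tests and summary t-tests, including printed-table checks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylseq_dm as md
from methylseq_dm import published
from methylseq_dm.cohort_stats import GroupSummary


def _enumerate_2xc_pvalue(table):
    """Brute-force Freeman-Halton for a 2-row table: enumerate first-row fills."""
    t = np.asarray(table)
    rows, cols = t.sum(1), t.sum(0)
    n = t.sum()

    def logp(tab):
        lg = math.lgamma
        return (sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols)
                - lg(n + 1) - sum(lg(x + 1) for x in np.ravel(tab)))

    obs = logp(t)
    total = p_le = 0.0
    ranges = [range(int(c) + 1) for c in cols]
    for fill in itertools.product(*ranges):
        if sum(fill) != rows[0]:
            continue
        tab = np.array([fill, cols - np.array(fill)])
        if (tab < 0).any():
            continue
        pr = math.exp(logp(tab))
        total += pr
        if logp(tab) <= obs + 1e-9:
            p_le += pr
    return p_le / total


class TestFisher2x2:
    @pytest.mark.parametrize("table,expected", [
        (published.INFANT_SEX_TABLE, 0.82),
        (published.DELIVERY_ROUTE_TABLE, 0.46),
        (published.SUBGROUP_INFANT_SEX_TABLE, 0.51),
    ])
    def test_printed_cohort_values(self, table, expected):
        assert md.fisher_exact_2x2(table) == pytest.approx(expected, abs=0.005)

    def test_diagonal_table_full_enumeration(self):
        # [[5,0],[0,5]]: only extreme tables as improbable -> 2/C(10,5)
        assert md.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_balanced_table_p_one(self):
        assert md.fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_convention(self):
        assert md.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


class TestFisherRxc:
    @pytest.mark.parametrize("table", [
        [[17, 19], [19, 18]], [[5, 0], [0, 5]], [[2, 7], [8, 2]],
    ])
    def test_matches_2x2_implementation(self, table):
        assert md.fisher_exact_rxc(table)["p"] == pytest.approx(
            md.fisher_exact_2x2(table), abs=1e-9)

    @pytest.mark.parametrize("table", [
        [[1, 2, 3], [3, 2, 1]],
        [[3, 7, 26], [3, 5, 29]],
        [[4, 1, 0], [1, 3, 3]],
    ])
    def test_exact_matches_enumeration_oracle(self, table):
        assert md.fisher_exact_rxc(table)["p"] == pytest.approx(
            _enumerate_2xc_pvalue(table), abs=1e-9)

    def test_enumerated_probabilities_sum_to_one(self):
        # indirectly: p of the most probable table plus complement is consistent;
        # direct check via oracle machinery
        t = [[2, 3], [4, 1]]
        assert _enumerate_2xc_pvalue([[5, 0], [0, 5]]) == pytest.approx(2 / 252)
        assert md.fisher_exact_rxc(t)["p"] <= 1.0

    def test_montecarlo_close_to_exact(self):
        table = [[3, 7, 26], [3, 5, 29]]
        exact = md.fisher_exact_rxc(table)["p"]
        mc1 = md.fisher_exact_rxc(table, method="montecarlo", n_sim=4000, seed=1)
        mc2 = md.fisher_exact_rxc(table, method="montecarlo", n_sim=4000, seed=2)
        assert abs(mc1["p"] - exact) < 3 * mc1["se"] + 1e-3
        assert abs(mc1["p"] - mc2["p"]) < 3 * (mc1["se"] + mc2["se"])

    def test_cap_exceeded_suggests_montecarlo(self):
        big = (np.ones((4, 4), int) * 40).tolist()
        with pytest.raises(ValueError, match="montecarlo"):
            md.fisher_exact_rxc(big, max_tables=100)


class TestChiSquare:
    def test_printed_smoking_row(self):
        r = md.chi_square(published.SMOKING_TABLE)
        assert r["p"] == pytest.approx(0.79, abs=0.005)

    def test_observed_equals_expected(self):
        r = md.chi_square([[10, 20], [10, 20]])
        assert r["chi2"] == pytest.approx(0.0, abs=1e-12) and r["p"] == 1.0

    def test_yates_closed_form(self):
        r = md.chi_square([[10, 20], [20, 10]], yates=True)
        # N(|ad-bc|-N/2)^2 / (r1 r2 c1 c2) = 60*270^2/810000
        assert r["chi2"] == pytest.approx(5.4)

    def test_transposition_invariance(self):
        t = [[3, 7, 26], [3, 5, 29]]
        assert md.chi_square(t)["chi2"] == pytest.approx(
            md.chi_square(np.array(t).T.tolist())["chi2"])

    def test_yates_needs_2x2(self):
        with pytest.raises(ValueError):
            md.chi_square([[1, 2, 3], [4, 5, 6]], yates=True)


class TestTTest:
    @pytest.mark.parametrize("a,b,expected", [
        (published.MATERNAL_BMI, None, 0.81),
        (published.GESTATIONAL_AGE, None, 0.79),
    ])
    def test_printed_numeric_rows(self, a, b, expected):
        g1, g2 = a
        assert md.t_test_summary(g1, g2)["p"] == pytest.approx(expected, abs=0.005)

    def test_identical_summaries(self):
        g = GroupSummary(10.0, 2.0, 20)
        r = md.t_test_summary(g, g)
        assert r["t"] == 0.0 and r["p"] == 1.0

    def test_matches_raw_data_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5, 2, 30)
        y = rng.normal(5.5, 2.5, 25)
        summ = md.t_test_summary(GroupSummary(x.mean(), x.std(ddof=1), 30),
                                 GroupSummary(y.mean(), y.std(ddof=1), 25))
        t_raw, p_raw = stats.ttest_ind(x, y)
        assert summ["t"] == pytest.approx(t_raw, rel=1e-10)
        assert summ["p"] == pytest.approx(p_raw, rel=1e-10)
        welch = md.t_test_summary(GroupSummary(x.mean(), x.std(ddof=1), 30),
                                  GroupSummary(y.mean(), y.std(ddof=1), 25),
                                  variance="welch")
        t_w, p_w = stats.ttest_ind(x, y, equal_var=False)
        assert welch["p"] == pytest.approx(p_w, rel=1e-10)


class TestCohortTable:
    def test_identical_groups_all_null(self):
        half = pd.DataFrame({"sample_id": [f"a{i}" for i in range(12)],
                             "group": "case",
                             "age": np.r_[np.full(6, 30.0), np.full(6, 35.0)],
                             "sex": ["M", "F"] * 6})
        other = half.assign(sample_id=[f"b{i}" for i in range(12)], group="control")
        tab = md.cohort_table(pd.concat([half, other]), "group",
                              numeric=["age"], categorical=["sex"])
        assert (tab["p"] == 1.0).all()

    def test_planted_imbalance_detected(self):
        rng = np.random.default_rng(11)
        n = 40
        sheet = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(2 * n)],
            "group": ["case"] * n + ["control"] * n,
            "age": np.r_[rng.normal(34, 3, n), rng.normal(30, 3, n)],
            "bmi": rng.normal(25, 4, 2 * n),
            "sex": rng.choice(["M", "F"], 2 * n),
        })
        tab = md.cohort_table(sheet, "group", numeric=["age", "bmi"],
                              categorical=["sex"]).set_index("variable")
        assert tab.loc["age", "p"] < 0.01
        assert tab.loc["bmi", "p"] > 0.05

    def test_single_variable_sheet(self, small_cohort):
        tab = md.cohort_table(small_cohort["sheet"], "group",
                              numeric=["maternal_age"])
        assert len(tab) == 1 and tab.iloc[0]["test"] == "t_pooled"
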