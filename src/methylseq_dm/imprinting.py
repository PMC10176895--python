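"""Imprinting-control-region (ICR) methylation analysis.

ICRs are germline or secondary differentially methylated regions expected to
sit near 50% methylation in somatic tissue.  To avoid skew from missing
data, methylation is first averaged across samples separately at each CpG
within each (group x sex) cell; those per-CpG means are then the observation
unit of a 2x2 factorial ANOVA (group, sex, interaction) with
Bonferroni-corrected within-sex group contrasts.  Direction tallies and
capture-coverage fractions across an ICR catalogue are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .matrix import MethylomeMatrix


@dataclass
class ICRDefinition:
    name: str
    chrom: str
    start: int   # 0-based half-open interval
    end: int
    parental_origin: str = "maternal"    # maternal | paternal
    icr_type: str = "oocyte_gametic"     # oocyte_gametic | sperm_gametic | secondary
    n_cpgs_total: int = 0                # CpGs existing in the region genome-wide

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"ICR {self.name}: invalid interval")


@dataclass
class ICRSummary:
    """Per-CpG per-(group x sex) mean betas for one ICR."""

    icr: ICRDefinition
    cell_means: pd.DataFrame       # index (chrom,pos); columns like 'case_M', 'control_F'
    n_cpgs_captured: int
    coverage_fraction: float       # captured / n_cpgs_total (NaN if total unknown)

    def group_difference(self, sex: str | None = None) -> pd.Series:
        """Per-CpG case-minus-control mean difference, optionally within one sex."""
        if sex is None:
            case = self.cell_means[[c for c in self.cell_means if c.startswith("case")]].mean(axis=1)
            ctrl = self.cell_means[[c for c in self.cell_means if c.startswith("control")]].mean(axis=1)
        else:
            case = self.cell_means[f"case_{sex}"]
            ctrl = self.cell_means[f"control_{sex}"]
        return case - ctrl


def _sites_in(matrix: MethylomeMatrix, icr: ICRDefinition) -> np.ndarray:
    s = matrix.sites
    hit = (s["chrom"] == icr.chrom) & (s["pos"] >= icr.start) & (s["pos"] < icr.end)
    return np.flatnonzero(hit.to_numpy())


def summarize_icr(matrix: MethylomeMatrix, icr: ICRDefinition,
                  samplesheet: pd.DataFrame, group_col: str = "group",
                  case: str = "case", control: str = "control") -> ICRSummary:
    """Per-CpG mean beta over non-missing samples in each (group x sex) cell."""
    idx = _sites_in(matrix, icr)
    sheet = samplesheet.set_index("sample_id")
    cols = {}
    sub = matrix.take_sites(idx)
    beta = sub.beta() if len(idx) else np.empty((0, matrix.n_samples))
    for grp in (case, control):
        for sex in ("M", "F"):
            ids = sheet.index[(sheet[group_col] == grp) & (sheet["sex"] == sex)]
            j = [matrix.samples.index(s) for s in ids if s in matrix.samples]
            label = f"{'case' if grp == case else 'control'}_{sex}"
            if len(idx) and j:
                with np.errstate(invalid="ignore"):
                    cols[label] = np.nanmean(beta[:, j], axis=1)
            else:
                cols[label] = np.full(len(idx), np.nan)
    cm = pd.DataFrame(cols, index=pd.MultiIndex.from_frame(sub.sites[["chrom", "pos"]])
                      if len(idx) else None)
    frac = len(idx) / icr.n_cpgs_total if icr.n_cpgs_total else np.nan
    return ICRSummary(icr=icr, cell_means=cm, n_cpgs_captured=len(idx),
                      coverage_fraction=frac)


def icr_anova(summary: ICRSummary) -> dict:
    """Two-way factorial ANOVA on per-CpG cell means, CpGs as replicates.

    Type II sums of squares (robust to mild unbalance from per-cell
    missingness); within-sex group contrasts are two-sample t-tests across
    CpG means with a Bonferroni factor of 2.
    """
    cm = summary.cell_means.dropna()
    if len(cm) < 2:
        raise ValueError("ICR ANOVA needs at least 2 captured CpGs")
    long = cm.reset_index(drop=True).melt(var_name="cell", value_name="beta")
    long[["group", "sex"]] = long["cell"].str.split("_", expand=True)
    if long["beta"].std(ddof=0) == 0:
        return {"degenerate": True, "F_group": 0.0, "p_group": 1.0,
                "F_sex": 0.0, "p_sex": 1.0, "F_interaction": 0.0,
                "p_interaction": 1.0, "p_male": 1.0, "p_female": 1.0}
    fit = ols("beta ~ C(group) * C(sex)", data=long).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    res = {
        "degenerate": False,
        "F_group": float(tab.loc["C(group)", "F"]),
        "p_group": float(tab.loc["C(group)", "PR(>F)"]),
        "F_sex": float(tab.loc["C(sex)", "F"]),
        "p_sex": float(tab.loc["C(sex)", "PR(>F)"]),
        "F_interaction": float(tab.loc["C(group):C(sex)", "F"]),
        "p_interaction": float(tab.loc["C(group):C(sex)", "PR(>F)"]),
    }
    for sex, key in (("M", "p_male"), ("F", "p_female")):
        a = cm[f"case_{sex}"]
        b = cm[f"control_{sex}"]
        _, p = stats.ttest_ind(a, b)
        res[key] = float(min(1.0, 2 * p))  # Bonferroni over the two sexes
    return res


def icr_direction_tally(matrix: MethylomeMatrix, icrs: list[ICRDefinition],
                        samplesheet: pd.DataFrame, **kw) -> pd.DataFrame:
    """Per-ICR signed mean difference (combined and per sex) with tallies.

    ICRs capturing zero CpGs are excluded from denominators ("with data").
    The returned frame carries attrs: n_with_data, n_hypo, n_hyper,
    n_female_below_male, n_opposite_f_hypo_m_hyper.
    """
    rows = []
    for icr in icrs:
        s = summarize_icr(matrix, icr, samplesheet, **kw)
        if s.n_cpgs_captured == 0:
            continue
        rows.append({
            "icr": icr.name,
            "n_cpgs": s.n_cpgs_captured,
            "diff_combined": float(s.group_difference().mean()),
            "diff_male": float(s.group_difference("M").mean()),
            "diff_female": float(s.group_difference("F").mean()),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out.attrs["n_with_data"] = len(out)
        out.attrs["n_hypo"] = int((out["diff_combined"] < 0).sum())
        out.attrs["n_hyper"] = int((out["diff_combined"] > 0).sum())
        out.attrs["n_female_below_male"] = int((out["diff_female"] < out["diff_male"]).sum())
        out.attrs["n_opposite_f_hypo_m_hyper"] = int(
            ((out["diff_female"] < 0) & (out["diff_male"] > 0)).sum())
    return out


def icr_coverage(icrs: list[ICRDefinition], captured_sites: pd.DataFrame,
                 comparison_sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fraction of each ICR's total CpGs present in one or two site sets."""
    def _count(sites: pd.DataFrame, icr: ICRDefinition) -> int:
        hit = ((sites["chrom"] == icr.chrom) & (sites["pos"] >= icr.start)
               & (sites["pos"] < icr.end))
        return int(hit.sum())

    rows = []
    for icr in icrs:
        row = {"icr": icr.name, "n_cpgs_total": icr.n_cpgs_total}
        n1 = _count(captured_sites, icr)
        row["n_captured"] = n1
        row["frac_captured"] = n1 / icr.n_cpgs_total if icr.n_cpgs_total else np.nan
        if comparison_sites is not None:
            n2 = _count(comparison_sites, icr)
            row["n_comparison"] = n2
            row["frac_comparison"] = n2 / icr.n_cpgs_total if icr.n_cpgs_total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
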