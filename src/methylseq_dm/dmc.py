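"""Per-CpG differential methylation testing.

At each CpG a binomial logistic regression of (methylated, unmethylated)
read counts on intercept + group contrast + covariates is fitted by
iteratively reweighted least squares, using only samples non-missing at that
site.  The group coefficient's Wald z test gives the per-site p-value;
p-values are converted jointly to Storey q-values (pi0 estimated by a
lambda-grid smoother, or fixed at 1 for exact Benjamini-Hochberg
behaviour).  A CpG is a DMC when q < 0.05 (default).

Sites that fail to converge or show complete separation are marked
untestable and excluded from the q-value computation (keeping the null
distribution of tested sites uniform); their count is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import MethylomeMatrix

log = logging.getLogger(__name__)

MAX_IRLS_ITER = 50
IRLS_TOL = 1e-8
SEPARATION_COEF = 20.0  # |log-odds| beyond this flags quasi-separation


@dataclass
class DesignSpec:
    """Which contrast to test, on which samples, with which covariates.

    ``covariates`` may contain sample-sheet column names (e.g. ``sex``,
    ``complications``) and the token ``cells``, which expands to all
    estimated cell-proportion columns.  ``sample_subset`` restricts to one
    sex ('males'/'females'); sex is then dropped from the covariates.
    """

    group_col: str = "group"
    case: str = "case"
    control: str = "control"
    covariates: tuple[str, ...] = ("sex",)
    sample_subset: str = "all"

    def __post_init__(self) -> None:
        if self.sample_subset not in ("all", "males", "females"):
            raise ValueError("sample_subset must be all|males|females")

    @property
    def name(self) -> str:
        tag = f"{self.case}_vs_{self.control}"
        if self.sample_subset != "all":
            tag += f"_{self.sample_subset}"
        return tag


def build_design(samplesheet: pd.DataFrame, design: DesignSpec,
                 proportions: pd.DataFrame | None = None,
                 ) -> tuple[list[str], np.ndarray, list[str]]:
    """Design matrix for the requested contrast.

    Returns (sample ids in matrix-column order to use, X, column names);
    X's second column is the case indicator being tested.
    """
    sheet = samplesheet.set_index("sample_id", drop=False)
    sel = sheet[design.group_col].isin([design.case, design.control])
    if design.sample_subset == "males":
        sel &= sheet["sex"] == "M"
    elif design.sample_subset == "females":
        sel &= sheet["sex"] == "F"
    sheet = sheet[sel]
    for lvl in (design.case, design.control):
        if not (sheet[design.group_col] == lvl).any():
            raise ValueError(f"contrast level {lvl!r} absent from the sample subset")
    ids = list(sheet["sample_id"])
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(ids)),
        "contrast": (sheet[design.group_col] == design.case).to_numpy(float),
    }
    for cov in design.covariates:
        if cov == "sex":
            if design.sample_subset != "all":
                continue  # constant within a sex-stratified subset
            cols["sex_M"] = (sheet["sex"] == "M").to_numpy(float)
        elif cov == "cells":
            if proportions is None:
                raise ValueError("'cells' covariate requested but no proportions given")
            prop_cols = [c for c in proportions.columns if c != "residual_norm"]
            P = proportions.loc[ids, prop_cols].to_numpy(float)
            for k, c in enumerate(prop_cols):
                cols[f"cell_{c}"] = P[:, k]
        else:
            v = sheet[cov].to_numpy(float)
            if np.ptp(v) == 0:
                raise ValueError(f"covariate {cov!r} is constant in the subset")
            cols[cov] = v
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    # proportions as produced need not sum to 1, but can be nearly collinear
    # with the intercept; drop the last proportion column if ill-conditioned
    if np.linalg.cond(X) > 1e10:
        cell_cols = [i for i, c in enumerate(names) if c.startswith("cell_")]
        if cell_cols:
            drop = cell_cols[-1]
            log.warning("design matrix ill-conditioned; dropping %s", names[drop])
            X = np.delete(X, drop, axis=1)
            names.pop(drop)
    return ids, X, names


def _binom_deviance(m, t, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(m > 0, m * np.log(m / (t * mu)), 0.0)
        r = t - m
        b = np.where(r > 0, r * np.log(r / (t * (1 - mu))), 0.0)
    return 2.0 * (a + b).sum()


def fit_site_glm(m: np.ndarray, t: np.ndarray, X: np.ndarray,
                 ) -> tuple[float, float, float, float, bool]:
    """Binomial logistic IRLS at one site.

    Returns (coef, se, z, p, ok) for X's second column (the contrast);
    ok=False marks non-convergence, separation, or a singular system.
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    n, p = X.shape
    if n < p:
        return np.nan, np.nan, np.nan, np.nan, False
    beta = np.zeros(p)
    p_bar = (m.sum() + 0.5) / (t.sum() + 1.0)
    beta[0] = np.log(p_bar / (1 - p_bar))
    y = m / t
    dev_old = np.inf
    ok = False
    A = None
    for _ in range(MAX_IRLS_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = t * mu * (1 - mu)
        z_work = eta + (y - mu) / (mu * (1 - mu))
        XW = X * w[:, None]
        A = X.T @ XW
        try:
            beta = np.linalg.solve(A, XW.T @ z_work)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, np.nan, np.nan, False
        dev = _binom_deviance(m, t, np.clip(1 / (1 + np.exp(-np.clip(X @ beta, -30, 30))),
                                            1e-10, 1 - 1e-10))
        if abs(dev - dev_old) < IRLS_TOL * (abs(dev) + 0.1):
            ok = True
            break
        dev_old = dev
    if not ok or abs(beta[1]) > SEPARATION_COEF:
        return float(beta[1]), np.nan, np.nan, np.nan, False
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return float(beta[1]), np.nan, np.nan, np.nan, False
    se = float(np.sqrt(cov[1, 1]))
    coef = float(beta[1])
    zval = coef / se
    pval = 2.0 * norm.sf(abs(zval))
    return coef, se, zval, float(pval), True


def qvalues(p: np.ndarray, pi0_mode: str = "smoother") -> np.ndarray:
    """Storey q-values.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) by a cubic
    least-squares smoother evaluated at lambda=0.95 and clamped to (0, 1]
    ('smoother'), or fixed at 1 ('fixed_one', which makes the result exactly
    Benjamini-Hochberg).
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1] with no NaN")
    m = p.size
    if pi0_mode == "fixed_one":
        pi0 = 1.0
    elif pi0_mode == "smoother":
        lams = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lams])
        if m < 100:
            pi0 = 1.0  # too few p-values for a stable smoother
        else:
            coefs = np.polyfit(lams, pi0_l, deg=3)
            pi0 = float(np.polyval(coefs, 0.95))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError("pi0_mode must be 'fixed_one' or 'smoother'")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def methylation_difference(matrix: MethylomeMatrix, case_ids, control_ids) -> np.ndarray:
    """Per-site mean beta over case samples minus mean over controls.

    Group means use non-missing samples only; a site where either group has
    no non-missing sample gets NaN.
    """
    beta = matrix.beta()
    ci = [matrix.samples.index(s) for s in case_ids]
    gi = [matrix.samples.index(s) for s in control_ids]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices -> NaN
        return np.nanmean(beta[:, ci], axis=1) - np.nanmean(beta[:, gi], axis=1)


DIFF_BINS = ((0.0, 0.10, "<10%"), (0.10, 0.20, "10-20%"), (0.20, np.inf, ">20%"))


def call_dmcs(matrix: MethylomeMatrix, samplesheet: pd.DataFrame,
              design: DesignSpec, q_threshold: float = 0.05,
              proportions: pd.DataFrame | None = None,
              pi0_mode: str = "smoother") -> "DMCResult":
    """Run the per-site GLM battery for one design and call DMCs at q < threshold."""
    ids, X, colnames = build_design(samplesheet, design, proportions)
    cols = np.array([matrix.samples.index(s) for s in ids])
    sheet = samplesheet.set_index("sample_id")
    is_case = (sheet.loc[ids, design.group_col] == design.case).to_numpy()

    M = matrix.m[:, cols].astype(float)
    T = matrix.t[:, cols].astype(float)
    OK = ~matrix.mask[:, cols]

    n_sites = matrix.n_sites
    coef = np.full(n_sites, np.nan)
    se = np.full(n_sites, np.nan)
    zst = np.full(n_sites, np.nan)
    pv = np.full(n_sites, np.nan)
    tested = np.zeros(n_sites, dtype=bool)
    n_failed = 0
    for i in range(n_sites):
        use = OK[i]
        if not (use & is_case).any() or not (use & ~is_case).any():
            continue
        Xi = X[use]
        if np.ptp(Xi[:, 1]) == 0:
            continue
        c, s, z, p, ok = fit_site_glm(M[i, use], T[i, use], Xi)
        if ok:
            coef[i], se[i], zst[i], pv[i] = c, s, z, p
            tested[i] = True
        else:
            n_failed += 1
    if n_failed:
        log.info("%d sites untestable (separation/non-convergence), excluded from q-values",
                 n_failed)

    q = np.full(n_sites, np.nan)
    if tested.any():
        q[tested] = qvalues(pv[tested], pi0_mode=pi0_mode)

    case_ids = [s for s, c in zip(ids, is_case) if c]
    ctrl_ids = [s for s, c in zip(ids, is_case) if not c]
    diff = methylation_difference(matrix.take_samples(ids), case_ids, ctrl_ids)

    results = matrix.sites.copy()
    results["coef"] = coef
    results["se"] = se
    results["z"] = zst
    results["p"] = pv
    results["q"] = q
    results["meth_diff"] = diff
    results["direction"] = np.where(diff > 0, "hyper", "hypo")
    results["tested"] = tested
    results["n_case"] = OK[:, is_case].sum(axis=1)
    results["n_control"] = OK[:, ~is_case].sum(axis=1)

    dmcs = results[tested & (q < q_threshold)].reset_index(drop=True)
    return DMCResult(design=design, results=results, dmcs=dmcs,
                     n_untestable=n_failed, q_threshold=q_threshold)


@dataclass
class DMCResult:
    design: DesignSpec
    results: pd.DataFrame   # full per-site table
    dmcs: pd.DataFrame      # q < threshold subset
    n_untestable: int
    q_threshold: float

    def summary(self) -> dict:
        d = self.dmcs
        absd = d["meth_diff"].abs()
        bins = {lab: int(((absd >= lo) & (absd < hi)).sum()) for lo, hi, lab in DIFF_BINS}
        return {
            "design": self.design.name,
            "n_tested": int(self.results["tested"].sum()),
            "n_untestable": self.n_untestable,
            "n_dmcs": len(d),
            "n_hypo": int((d["direction"] == "hypo").sum()),
            "n_hyper": int((d["direction"] == "hyper").sum()),
            "diff_bins": bins,
        }


def compare_dmc_sets(a: pd.DataFrame, b: pd.DataFrame,
                     tolerance: float = 0.05) -> dict:
    """Overlap/direction/magnitude concordance between two DMC tables.

    Tables are keyed by (chrom, pos) and must carry ``meth_diff``.  Among
    shared sites, 'similar magnitude' means |diff_a - diff_b| <= tolerance
    (the +/-5% rule by default).
    """
    ka = pd.MultiIndex.from_frame(a[["chrom", "pos"]])
    kb = pd.MultiIndex.from_frame(b[["chrom", "pos"]])
    shared = ka.intersection(kb)
    da = a.set_index(["chrom", "pos"]).loc[shared, "meth_diff"]
    db = b.set_index(["chrom", "pos"]).loc[shared, "meth_diff"]
    same_dir = int((np.sign(da) == np.sign(db)).sum())
    return {
        "n_a": len(a), "n_b": len(b), "n_shared": len(shared),
        "n_a_only": len(a) - len(shared), "n_b_only": len(b) - len(shared),
        "frac_a_shared": len(shared) / len(a) if len(a) else np.nan,
        "frac_b_shared": len(shared) / len(b) if len(b) else np.nan,
        # two conventions for 'shared of total': union and summed list sizes
        "frac_of_union": len(shared) / len(ka.union(kb)) if len(a) + len(b) else np.nan,
        "frac_of_sum": len(shared) / (len(a) + len(b)) if len(a) + len(b) else np.nan,
        "n_same_direction": same_dir,
        "n_opposite_direction": len(shared) - same_dir,
        "n_similar_magnitude": int(((da - db).abs() <= tolerance).sum()),
    }
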