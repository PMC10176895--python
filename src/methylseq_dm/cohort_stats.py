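"""Small-table demographic statistics.

Exact and asymptotic contingency tests plus summary-statistic t-tests, the
tools used for cohort-description tables: two-sided Fisher exact (2x2 by the
hypergeometric "probability at most the observed table" rule; r x c by the
Freeman-Halton extension with exact enumeration or a seeded Monte-Carlo
estimate), Pearson chi-square with optional Yates correction, and unpaired
t-tests computed from mean/SD/n summaries (pooled by default, Welch
available).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TIE_REL_TOL = 1e-7


def _as_2d_int(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = np.round(t).astype(np.int64)
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all margin-consistent tables whose
    probability is at most that of the observed table (with a small relative
    tie tolerance) — the convention of the standard R implementation.  A
    zero row or column margin returns p = 1.
    """
    t = _as_2d_int(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def _log_table_prob(t: np.ndarray, lgr, lgc, lgn) -> float:
    # multivariate hypergeometric log-probability with fixed margins
    return (lgr.sum() + lgc.sum() - lgn
            - sum(math.lgamma(x + 1) for x in t.flat))


def fisher_exact_rxc(table, method: str = "exact", n_sim: int = 20_000,
                     seed: int = 0, max_tables: int = 2_000_000) -> dict:
    """Freeman-Halton exact test for an r x c table.

    method='exact' enumerates all tables with the observed margins (error if
    the enumeration would exceed ``max_tables``); method='montecarlo' samples
    ``n_sim`` tables with fixed margins and reports the estimate with its
    binomial standard error.
    """
    t = _as_2d_int(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    if (rows == 0).any() or (cols == 0).any():
        return {"p": 1.0, "method": method, "degenerate": True}
    lgr = np.array([math.lgamma(x + 1) for x in rows])
    lgc = np.array([math.lgamma(x + 1) for x in cols])
    lgn = math.lgamma(n + 1)
    obs_logp = _log_table_prob(t, lgr, lgc, lgn)
    cutoff = obs_logp + abs(obs_logp) * TIE_REL_TOL + 1e-12

    if method == "exact":
        r, c = t.shape
        total_logp = []
        count = 0

        def rec(i: int, col_rem: np.ndarray, cur: list[np.ndarray]) -> None:
            nonlocal count
            if i == r - 1:
                last = col_rem
                if (last >= 0).all():
                    count += 1
                    if count > max_tables:
                        raise ValueError(
                            "exact enumeration too large; use method='montecarlo'")
                    full = np.vstack(cur + [last])
                    total_logp.append(_log_table_prob(full, lgr, lgc, lgn))
                return
            for combo in _row_fills(int(rows[i]), col_rem):
                rec(i + 1, col_rem - combo, cur + [combo])

        def _row_fills(row_total: int, col_rem: np.ndarray):
            c_ = len(col_rem)

            def gen(j: int, rem: int, acc: list[int]):
                if j == c_ - 1:
                    if rem <= col_rem[j]:
                        yield np.array(acc + [rem])
                    return
                for v in range(min(rem, int(col_rem[j])) + 1):
                    yield from gen(j + 1, rem - v, acc + [v])

            yield from gen(0, row_total, [])

        rec(0, cols.copy(), [])
        logps = np.array(total_logp)
        probs = np.exp(logps - logps.max())
        total = probs.sum()
        p = probs[logps <= cutoff].sum() / total
        return {"p": float(min(p, 1.0)), "method": "exact", "n_tables": count,
                "degenerate": False}

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_sim):
            sim = _sample_fixed_margins(rows, cols, rng)
            if _log_table_prob(sim, lgr, lgc, lgn) <= cutoff:
                hits += 1
        # add-one estimator keeps p > 0
        p = (hits + 1) / (n_sim + 1)
        se = math.sqrt(p * (1 - p) / n_sim)
        return {"p": float(p), "se": se, "method": "montecarlo", "n_sim": n_sim,
                "degenerate": False}
    raise ValueError("method must be 'exact' or 'montecarlo'")


def _sample_fixed_margins(rows: np.ndarray, cols: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Random table with the given margins (sequential multivariate hypergeometric)."""
    r, c = len(rows), len(cols)
    out = np.zeros((r, c), dtype=np.int64)
    col_rem = cols.copy()
    for i in range(r - 1):
        draw = rng.multivariate_hypergeometric(col_rem, int(rows[i]))
        out[i] = draw
        col_rem = col_rem - draw
    out[r - 1] = col_rem
    return out


def chi_square(table, yates: bool = False) -> dict:
    """Pearson chi-square with df=(r-1)(c-1); Yates correction for 2x2 only."""
    t = _as_2d_int(table)
    if yates and t.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    exp = stats.contingency.expected_freq(t)
    if (exp == 0).any():
        return {"chi2": np.nan, "df": np.nan, "p": np.nan, "degenerate": True}
    chi2, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return {"chi2": float(chi2), "df": int(df), "p": float(p), "degenerate": False}


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2 or not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("need n >= 2 and finite nonnegative sd")


def t_test_summary(a: GroupSummary, b: GroupSummary,
                   variance: str = "pooled") -> dict:
    """Two-sided unpaired t-test from group summaries (pooled or Welch)."""
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return {"t": 0.0, "df": a.n + b.n - 2, "p": 1.0}
        return {"t": np.inf, "df": a.n + b.n - 2, "p": 0.0}
    equal_var = variance == "pooled"
    if variance not in ("pooled", "welch"):
        raise ValueError("variance must be 'pooled' or 'welch'")
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                      equal_var=equal_var)
    if equal_var:
        df = a.n + b.n - 2
    else:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return {"t": float(t), "df": float(df), "p": float(p)}


def cohort_table(samplesheet: pd.DataFrame, group_col: str,
                 numeric: list[str] = (), categorical: list[str] = (),
                 ) -> pd.DataFrame:
    """Per-variable group comparison in the style of a cohort-description table.

    Numeric variables: mean (SD) per group, pooled t-test on complete cases.
    Categorical: per-level counts; Fisher exact when any expected cell < 5
    (exact r x c via Freeman-Halton), else plain chi-square.
    """
    groups = sorted(samplesheet[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("cohort_table compares exactly two groups")
    g0 = samplesheet[samplesheet[group_col] == groups[0]]
    g1 = samplesheet[samplesheet[group_col] == groups[1]]
    rows = []
    for var in numeric:
        a = g0[var].dropna()
        b = g1[var].dropna()
        res = t_test_summary(GroupSummary(a.mean(), a.std(ddof=1), len(a)),
                             GroupSummary(b.mean(), b.std(ddof=1), len(b)))
        rows.append({"variable": var, "test": "t_pooled",
                     groups[0]: f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                     groups[1]: f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                     "p": res["p"]})
    for var in categorical:
        levels = sorted(samplesheet[var].dropna().unique())
        tab = np.array([[int((g[var] == lv).sum()) for lv in levels]
                        for g in (g0, g1)])
        exp = stats.contingency.expected_freq(tab)
        if (exp < 5).any():
            try:
                res = fisher_exact_rxc(tab, method="exact")
                test = "fisher_exact"
            except ValueError:
                res = fisher_exact_rxc(tab, method="montecarlo")
                test = "fisher_montecarlo"
            p = res["p"]
        else:
            p = chi_square(tab)["p"]
            test = "chi_square"
        rows.append({"variable": var, "test": test,
                     groups[0]: "/".join(str(x) for x in tab[0]),
                     groups[1]: "/".join(str(x) for x in tab[1]),
                     "p": p})
    return pd.DataFrame(rows)
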