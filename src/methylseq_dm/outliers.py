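"""Epigenetic-outlier detection from PC1 gap structure.

Samples are projected onto principal components of the complete-case beta
matrix, sorted along PC1, and the n-1 consecutive gaps are tested for a
single mean shift ("at most one change"): the best split of the gap
sequence into two mean segments is accepted when the reduction in Gaussian
cost (residual sum of squares around segment means, unit variance — the
convention of the standard changepoint routine, which treats the data as
already on a standardized scale) exceeds an MBIC-style penalty 3*ln(m)
over the m gaps.  The samples strictly beyond the changepoint gap, on the
side with fewer samples, are the declared outliers; an interior split with
both sides at least half the cohort declares none.

The unit-variance cost presumes standardized data, so the score vector is
divided by its (population) standard deviation before gaps are taken.
Gaps between neighbouring standardized scores of a homogeneous cohort are
small fractions of unity and never approach the penalty, while a sample
shifted by many within-cluster standard deviations opens a gap whose
squared standardized size alone exceeds it.  (A variance-normalized
likelihood ratio over the gaps themselves is unusable here: spacings of
sorted Gaussian scores are heavy-tailed, so it flags a tail sample in
almost every homogeneous cohort.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import fisher_exact_2x2
from .matrix import MethylomeMatrix


def complete_case_sites(matrix: MethylomeMatrix) -> np.ndarray:
    """Indices of sites with zero missing cells (covered in every sample)."""
    return np.flatnonzero(~matrix.mask.any(axis=1))


def pca_scores(beta: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Sample scores from SVD of the site-centered complete-case beta matrix.

    ``beta``: (n_sites, n_samples) with no NaN.  Returns (n_samples, k)
    scores ordered by explained variance.  PC1 sign convention: oriented so
    the sample of maximum |score| is positive.  A constant matrix yields
    all-zero scores.
    """
    if np.isnan(beta).any():
        raise ValueError("pca_scores requires a complete-case beta matrix")
    X = beta.T  # samples x sites
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        k = n_components or min(X.shape)
        return np.zeros((X.shape[0], k))
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    k = n_components or scores.shape[1]
    scores = scores[:, :k]
    for j in range(scores.shape[1]):
        imax = np.argmax(np.abs(scores[:, j]))
        if scores[imax, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


@dataclass
class OutlierReport:
    pc1: pd.Series                 # per-sample PC1 score
    order: list[str]               # sample ids sorted by PC1
    gaps: np.ndarray               # n-1 consecutive differences
    changepoint: int | None        # index into gaps (0-based) of the separating gap
    statistic: float
    penalty_used: float
    outlier_ids: list[str]
    side: str                      # low | high | none

    def to_dict(self) -> dict:
        return {
            "pc1": self.pc1.to_dict(),
            "order": self.order,
            "gaps": self.gaps.tolist(),
            "changepoint": self.changepoint,
            "statistic": self.statistic,
            "penalty_used": self.penalty_used,
            "outlier_ids": self.outlier_ids,
            "side": self.side,
        }


def detect_outliers_amoc(pc1: pd.Series, penalty: float | str = "mbic",
                         ) -> OutlierReport:
    """Single-changepoint test on sorted-PC1 gap sizes.

    ``penalty='mbic'`` uses 3*ln(m) for m gaps; a float sets it directly.
    """
    n = len(pc1)
    if n < 4:
        raise ValueError("changepoint detection needs at least 4 samples")
    order = pc1.sort_values().index.tolist()
    sorted_scores = pc1.loc[order].to_numpy(float)
    scale = sorted_scores.std()  # population SD; unit-variance cost assumes it
    if scale == 0:
        return OutlierReport(pc1=pc1, order=order,
                             gaps=np.zeros(n - 1), changepoint=None,
                             statistic=0.0, penalty_used=np.nan,
                             outlier_ids=[], side="none")
    gaps = np.diff(sorted_scores) / scale
    m = len(gaps)
    pen = 3.0 * np.log(m) if penalty == "mbic" else float(penalty)

    total = gaps.sum()
    sq = (gaps ** 2).sum()
    rss0 = sq - total ** 2 / m
    best_stat, best_k = -np.inf, None
    if rss0 > 1e-12:
        csum = np.cumsum(gaps)
        csq = np.cumsum(gaps ** 2)
        for k in range(1, m):  # segments [0:k], [k:m]
            rss1 = (csq[k - 1] - csum[k - 1] ** 2 / k) + \
                   ((sq - csq[k - 1]) - (total - csum[k - 1]) ** 2 / (m - k))
            stat = rss0 - rss1  # unit-variance Gaussian cost reduction
            if stat > best_stat:
                best_stat, best_k = stat, k

    changepoint = None
    outliers: list[str] = []
    side = "none"
    if best_k is not None and best_stat > pen:
        k = best_k
        mean1 = gaps[:k].mean()
        mean2 = gaps[k:].mean()
        if mean2 > mean1:
            # elevated gaps at the high end; separating gap is the first of
            # segment 2, i.e. between sorted samples k and k+1 (0-based)
            gap_idx = k
            candidate = order[gap_idx + 1:]
            cand_side = "high"
        else:
            # elevated gaps at the low end; separating gap is the last of
            # segment 1, between sorted samples k-1 and k
            gap_idx = k - 1
            candidate = order[: gap_idx + 1]
            cand_side = "low"
        if len(candidate) < n / 2:
            changepoint = gap_idx
            outliers = candidate
            side = cand_side
        else:
            best_stat = float(best_stat)  # split accepted but both sides large
    return OutlierReport(pc1=pc1, order=order, gaps=gaps,
                         changepoint=changepoint,
                         statistic=float(best_stat if np.isfinite(best_stat) else 0.0),
                         penalty_used=pen, outlier_ids=list(outliers), side=side)


def detect_outliers(matrix: MethylomeMatrix, penalty: float | str = "mbic",
                    site_subset: np.ndarray | None = None) -> OutlierReport:
    """Complete-case sites -> PCA -> AMOC on PC1 gaps, in one call.

    ``site_subset`` restricts to given site indices first (e.g. ICR-only or
    array-subset replication runs); the detector itself is identical.
    """
    idx = complete_case_sites(matrix)
    if site_subset is not None:
        idx = np.intersect1d(idx, site_subset)
    if len(idx) == 0:
        raise ValueError("no complete-case sites available for PCA")
    beta = matrix.take_sites(idx).beta()
    scores = pca_scores(beta, n_components=1)
    pc1 = pd.Series(scores[:, 0], index=matrix.samples)
    return detect_outliers_amoc(pc1, penalty=penalty)


def outlier_enrichment(outlier_ids, samplesheet: pd.DataFrame,
                       factor: str = "group") -> dict:
    """Two-sided Fisher exact test of outlier status against a 2-level factor."""
    sheet = samplesheet.set_index("sample_id")
    is_out = sheet.index.isin(list(outlier_ids))
    levels = sorted(sheet[factor].unique())
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels")
    a = int((is_out & (sheet[factor] == levels[0])).sum())
    b = int((is_out & (sheet[factor] == levels[1])).sum())
    c = int((~is_out & (sheet[factor] == levels[0])).sum())
    d = int((~is_out & (sheet[factor] == levels[1])).sum())
    if a + b == 0:  # no outliers: degenerate by convention
        return {"table": [[a, b], [c, d]], "p": 1.0, "degenerate": True}
    p = fisher_exact_2x2([[a, b], [c, d]])
    return {"table": [[a, b], [c, d]], "p": p, "degenerate": False}
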