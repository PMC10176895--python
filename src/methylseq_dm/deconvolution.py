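"""Reference-based cell-type deconvolution of bulk methylomes.

Per-sample cell proportions are estimated by constrained projection: the
sample's beta vector over marker CpGs is regressed on the reference panel by
nonnegative least squares (no sum-to-one constraint, matching the projection
approach used for cord-blood composition covariates).  Before projection,
panel CpGs must be non-missing in at least 90% of samples (configurable) and
remaining missing betas are imputed with the mean of all other samples at
that CpG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .matrix import MethylomeMatrix


class PanelMismatchError(ValueError):
    pass


@dataclass
class ReferencePanel:
    """Methylation-fraction profile of purified cell types over marker CpGs."""

    cpgs: pd.DataFrame          # columns chrom, pos (0-based)
    cell_types: list[str]
    profile: np.ndarray         # (n_cpgs, n_cell_types), fractions in [0,1]

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if len(self.cell_types) < 2:
            raise ValueError("panel needs >= 2 cell types")
        if self.profile.shape != (len(self.cpgs), len(self.cell_types)):
            raise ValueError("profile shape does not match cpgs x cell_types")
        if ((self.profile < 0) | (self.profile > 1)).any():
            raise ValueError("panel fractions must lie in [0,1]")
        if self.cpgs.duplicated(["chrom", "pos"]).any():
            raise ValueError("panel CpGs must be unique")

    def to_tsv(self, path) -> None:
        df = self.cpgs.copy()
        df["pos"] = df["pos"] + 1  # 1-based in files
        for j, ct in enumerate(self.cell_types):
            df[ct] = self.profile[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        cts = [c for c in df.columns if c not in ("chrom", "pos")]
        cpgs = pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"].astype(int) - 1})
        return cls(cpgs, cts, df[cts].to_numpy(dtype=float))


def select_panel_sites(matrix: MethylomeMatrix, panel: ReferencePanel,
                       min_frac: float = 0.9) -> tuple[pd.DataFrame, ReferencePanel]:
    """Intersect matrix sites with panel CpGs, apply the coverage rule, impute.

    Keeps intersected CpGs non-missing in at least ``min_frac`` of samples;
    each remaining missing beta is imputed with the mean beta of all other
    samples at that CpG.  Returns a complete beta submatrix (CpG x sample)
    and the matching panel rows.
    """
    mat_keys = pd.MultiIndex.from_frame(matrix.sites[["chrom", "pos"]])
    pan_keys = pd.MultiIndex.from_frame(panel.cpgs[["chrom", "pos"]])
    locs = mat_keys.get_indexer(pan_keys)
    hit = locs >= 0
    if not hit.any():
        raise PanelMismatchError(
            "no panel CpGs found in the matrix; check that panel and matrix "
            "use the same genome build and coordinate convention")
    row_idx = locs[hit]
    panel_idx = np.flatnonzero(hit)
    beta = matrix.beta()[row_idx]                       # (n_panel_hits, n_samples)
    covered = ~np.isnan(beta)
    frac = covered.mean(axis=1)
    keep = frac >= min_frac
    beta, covered = beta[keep], covered[keep]
    panel_idx = panel_idx[keep]
    # mean-of-others imputation; CpGs missing everywhere were already dropped
    row_mean = np.nanmean(beta, axis=1)
    beta = np.where(covered, beta, row_mean[:, None])
    sub = pd.DataFrame(beta, columns=matrix.samples)
    sub.insert(0, "chrom", panel.cpgs["chrom"].to_numpy()[panel_idx])
    sub.insert(1, "pos", panel.cpgs["pos"].to_numpy()[panel_idx])
    retained = ReferencePanel(panel.cpgs.iloc[panel_idx].reset_index(drop=True),
                              panel.cell_types, panel.profile[panel_idx])
    return sub, retained


def estimate_proportions(beta_submatrix: pd.DataFrame,
                         panel: ReferencePanel,
                         normalize: bool = False) -> pd.DataFrame:
    """Per-sample NNLS projection onto the panel.

    Solves min ||y - X w||_2 subject to w >= 0 for each sample; proportions
    are reported as solved (they need not sum to 1) unless ``normalize``.
    Returns a DataFrame indexed by sample with one column per cell type plus
    ``residual_norm``.
    """
    X = panel.profile
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("reference panel is rank deficient; NNLS returns one "
                      "minimum-norm solution among the optima")
    sample_cols = [c for c in beta_submatrix.columns if c not in ("chrom", "pos")]
    Y = beta_submatrix[sample_cols].to_numpy(dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("beta submatrix rows must align with panel CpGs")
    out = np.empty((len(sample_cols), X.shape[1]))
    res = np.empty(len(sample_cols))
    for j in range(len(sample_cols)):
        w, r = nnls(X, Y[:, j])
        out[j], res[j] = w, r
    if normalize:
        tot = out.sum(axis=1, keepdims=True)
        out = np.divide(out, tot, out=np.zeros_like(out), where=tot > 0)
    df = pd.DataFrame(out, index=pd.Index(sample_cols, name="sample_id"),
                      columns=panel.cell_types)
    df["residual_norm"] = res
    return df


def deconvolve(matrix: MethylomeMatrix, panel: ReferencePanel,
               min_frac: float = 0.9, normalize: bool = False) -> pd.DataFrame:
    """Convenience wrapper: select/impute panel sites, then NNLS per sample."""
    sub, retained = select_panel_sites(matrix, panel, min_frac=min_frac)
    return estimate_proportions(sub, retained, normalize=normalize)
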