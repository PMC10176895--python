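"""CpG count-matrix data model, I/O and QC filtering.

The central object is :class:`MethylomeMatrix`: per-CpG, per-sample
(methylated, total) read counts from capture bisulfite sequencing with an
explicit missingness mask.  Coordinates are 0-based internally and in BED
intervals; TSV I/O uses 1-based positions (CpG-report convention).  Counts
are assumed pre-merged across the two strands of each CpG dinucleotide and
addressed by the forward-strand C.

The site-retention funnel applied to real capture data is reproduced by
:func:`apply_site_exclusions` (SNP / blacklist removal) and
:func:`apply_coverage_filter` (per-cell coverage window, minimum-sample
rule, sex-chromosome drop), in that fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class RegionSet:
    """Named set of BED intervals (0-based, half-open) with per-interval categories."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end, category

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        missing = req - set(self.intervals.columns)
        if missing:
            raise ValueError(f"RegionSet {self.name!r} missing columns: {sorted(missing)}")
        if "category" not in self.intervals.columns:
            self.intervals = self.intervals.assign(category=self.name)
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = self.intervals.iloc[i]
            raise ValueError(
                f"RegionSet {self.name!r}: empty/inverted interval "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        self.intervals = self.intervals.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
        df.columns = ["chrom", "start", "end", "category"][: df.shape[1]]
        return cls(name or str(path), df)

    def to_bed(self, path) -> None:
        self.intervals[["chrom", "start", "end", "category"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def trees(self) -> dict[str, IntervalTree]:
        """One interval tree per chromosome; data payload is the category label."""
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            out[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e), c)
                for s, e, c in zip(grp["start"], grp["end"], grp["category"])
            )
        return out


@dataclass
class FilterConfig:
    """Coverage/retention thresholds of the site funnel.

    ``min_cov``/``max_cov`` are inclusive bounds on per-cell total reads;
    cells outside the window are masked missing.  Sites non-missing in fewer
    than ``min_samples`` samples are dropped, then sex-chromosome sites if
    ``autosomes_only``.
    """

    min_cov: int = 15
    max_cov: int = 500
    min_samples: int = 30
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_cov <= self.max_cov):
            raise ValueError("require 1 <= min_cov <= max_cov")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


class MethylomeMatrix:
    """Per-CpG x per-sample (methylated, total) read counts with missingness.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom`` (str) and ``pos`` (0-based int),
        unique and sorted by (chrom, pos).
    samples : ordered sample identifiers.
    m, t : integer arrays of shape (n_sites, n_samples).
    mask : boolean array, True where the cell is missing.
    """

    def __init__(self, sites: pd.DataFrame, samples: Sequence[str],
                 m: np.ndarray, t: np.ndarray, mask: np.ndarray | None = None,
                 validate: bool = True):
        self.sites = sites.reset_index(drop=True)
        self.samples = list(samples)
        self.m = np.asarray(m)
        self.t = np.asarray(t)
        self.mask = (np.zeros(self.m.shape, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        if validate:
            self._validate()

    # -- construction / validation -------------------------------------------------
    def _validate(self) -> None:
        ns, nk = len(self.sites), len(self.samples)
        for name, arr in (("m", self.m), ("t", self.t), ("mask", self.mask)):
            if arr.shape != (ns, nk):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(ns, nk)}")
        dup = self.sites.duplicated(["chrom", "pos"])
        if dup.any():
            row = self.sites[dup].iloc[0]
            raise ValueError(f"duplicate site {row['chrom']}:{row['pos'] + 1}")
        key = self.sites[["chrom", "pos"]]
        if not key.equals(key.sort_values(["chrom", "pos"], ignore_index=True)):
            raise ValueError("sites must be sorted by (chrom, pos)")
        ok = self.mask
        if ((self.t < 0) & ~ok).any() or ((self.m < 0) & ~ok).any():
            raise ValueError("negative read counts")
        bad = (self.m > self.t) & ~self.mask
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"m > t at {self.sites['chrom'][i]}:{self.sites['pos'][i] + 1}, "
                f"sample {self.samples[j]} ({self.m[i, j]} > {self.t[i, j]})"
            )

    # -- basic views -----------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> pd.Index:
        return pd.Index(zip(self.sites["chrom"], self.sites["pos"]))

    def take_sites(self, idx: np.ndarray) -> "MethylomeMatrix":
        return MethylomeMatrix(self.sites.iloc[idx], self.samples,
                               self.m[idx], self.t[idx], self.mask[idx],
                               validate=False)

    def take_samples(self, which: Iterable[str]) -> "MethylomeMatrix":
        cols = [self.samples.index(s) for s in which]
        return MethylomeMatrix(self.sites, [self.samples[c] for c in cols],
                               self.m[:, cols], self.t[:, cols], self.mask[:, cols],
                               validate=False)

    def beta(self) -> np.ndarray:
        """Methylation fraction m/t; NaN where missing.  Errors on t=0 non-missing."""
        zero = (self.t == 0) & ~self.mask
        if zero.any():
            i, j = np.argwhere(zero)[0]
            raise ValueError(
                f"zero total reads at non-missing cell "
                f"{self.sites['chrom'][i]}:{self.sites['pos'][i] + 1}, sample {self.samples[j]}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.m / np.where(self.t == 0, 1, self.t)
        return np.where(self.mask, np.nan, b)

    # -- I/O ---------------------------------------------------------------------------
    def write_tsv(self, path) -> None:
        """TSV with chrom, pos (1-based) then <sample>_m, <sample>_t pairs; NA = missing."""
        cols: dict[str, object] = {"chrom": self.sites["chrom"],
                                   "pos": self.sites["pos"] + 1}
        for j, s in enumerate(self.samples):
            mj = self.m[:, j].astype(object)
            tj = self.t[:, j].astype(object)
            mj[self.mask[:, j]] = pd.NA
            tj[self.mask[:, j]] = pd.NA
            cols[f"{s}_m"] = mj
            cols[f"{s}_t"] = tj
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "MethylomeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if list(df.columns[:2]) != ["chrom", "pos"]:
            raise ValueError("matrix TSV must start with columns chrom, pos")
        pair_cols = list(df.columns[2:])
        if len(pair_cols) % 2 != 0:
            raise ValueError("expected <sample>_m/<sample>_t column pairs")
        samples = []
        for k in range(0, len(pair_cols), 2):
            cm, ct = pair_cols[k], pair_cols[k + 1]
            if not (cm.endswith("_m") and ct.endswith("_t") and cm[:-2] == ct[:-2]):
                raise ValueError(f"malformed sample columns {cm!r}/{ct!r}")
            samples.append(cm[:-2])
        sites = pd.DataFrame({"chrom": df["chrom"],
                              "pos": df["pos"].astype(int) - 1})
        if (sites["pos"] < 0).any():
            raise ValueError("positions must be >= 1 in files")
        m_raw = df[[f"{s}_m" for s in samples]].to_numpy(dtype=float)
        t_raw = df[[f"{s}_t" for s in samples]].to_numpy(dtype=float)
        mask = np.isnan(m_raw) | np.isnan(t_raw)
        m = np.where(mask, 0, m_raw).astype(np.int64)
        t = np.where(mask, 0, t_raw).astype(np.int64)
        return cls(sites, samples, m, t, mask)


# ---------------------------------------------------------------------------------
# funnel operations
# ---------------------------------------------------------------------------------

def apply_site_exclusions(matrix: MethylomeMatrix,
                          exclusions: Sequence[RegionSet]) -> MethylomeMatrix:
    """Drop every CpG whose 1-bp position falls in any exclusion interval.

    BED half-open semantics: a site at 0-based position p is removed when an
    interval [start, end) satisfies start <= p < end.  Site order preserved.
    """
    if not exclusions:
        return matrix.take_sites(np.arange(matrix.n_sites))
    drop = np.zeros(matrix.n_sites, dtype=bool)
    for regs in exclusions:
        trees = regs.trees()
        for chrom, grp in matrix.sites.groupby("chrom", sort=False):
            tree = trees.get(str(chrom))
            if tree is None:
                continue
            for i, p in zip(grp.index, grp["pos"]):
                if tree.overlaps_point(int(p)):
                    drop[i] = True
    return matrix.take_sites(np.flatnonzero(~drop))


def apply_coverage_filter(matrix: MethylomeMatrix,
                          cfg: FilterConfig | None = None) -> MethylomeMatrix:
    """Coverage window mask -> minimum-sample site drop -> sex-chromosome drop."""
    cfg = cfg or FilterConfig()
    out_of_window = (matrix.t < cfg.min_cov) | (matrix.t > cfg.max_cov)
    mask = matrix.mask | out_of_window
    n_ok = (~mask).sum(axis=1)
    keep = n_ok >= cfg.min_samples
    if cfg.autosomes_only:
        keep &= ~matrix.sites["chrom"].isin(SEX_CHROMS).to_numpy()
    idx = np.flatnonzero(keep)
    return MethylomeMatrix(matrix.sites.iloc[idx], matrix.samples,
                           matrix.m[idx], matrix.t[idx], mask[idx],
                           validate=False)


def coverage_cdf(matrix: MethylomeMatrix) -> pd.DataFrame:
    """Number of sites covered (non-missing) in >= k samples, k = 1..n_samples."""
    n_ok = (~matrix.mask).sum(axis=1)
    ks = np.arange(1, matrix.n_samples + 1)
    counts = [(n_ok >= k).sum() for k in ks]
    return pd.DataFrame({"k": ks, "n_sites": counts})


def beta_values(matrix: MethylomeMatrix) -> pd.DataFrame:
    """Per-(site, sample) beta table; NaN marks missing cells."""
    b = matrix.beta()
    out = pd.DataFrame(b, columns=matrix.samples)
    return pd.concat([matrix.sites.reset_index(drop=True), out], axis=1)
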