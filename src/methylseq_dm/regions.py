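"""Region-level analysis: DMR merging, site annotation, enrichment tests.

DMRs are built by a single left-to-right pass per chromosome and direction:
consecutive same-direction DMCs are chained while the positional gap is
<= 250 bp (inclusive); chains of >= 2 CpGs become DMRs and chains of length
one remain singleton DMCs.  Hypo- and hypermethylated DMCs are merged
separately and never join.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .matrix import RegionSet


def merge_dmrs(dmcs: pd.DataFrame, gap: int = 250,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge a DMC table (chrom, pos, direction, meth_diff) into DMRs.

    Returns (dmrs, singletons).  DMR size is end - start + 2 so the region
    spans the trailing CpG dinucleotide.  Input must be position-sorted
    within chromosomes.
    """
    for col in ("chrom", "pos", "direction"):
        if col not in dmcs.columns:
            raise ValueError(f"DMC table missing column {col!r}")
    grp_sorted = dmcs.groupby("chrom", sort=False)["pos"].is_monotonic_increasing
    if not bool(grp_sorted.all()):
        raise ValueError("DMCs must be sorted by position within each chromosome")
    dmr_rows, single_rows = [], []
    for (chrom, direction), grp in dmcs.groupby(["chrom", "direction"], sort=False):
        pos = grp["pos"].to_numpy()
        diffs = grp["meth_diff"].to_numpy() if "meth_diff" in grp else np.full(len(grp), np.nan)
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > gap:
                chain_pos = pos[start:i]
                chain_diff = diffs[start:i]
                if len(chain_pos) >= 2:
                    dmr_rows.append({
                        "chrom": chrom, "start": int(chain_pos[0]), "end": int(chain_pos[-1]),
                        "n_dmcs": len(chain_pos), "direction": direction,
                        "size_bp": int(chain_pos[-1] - chain_pos[0] + 2),
                        "mean_diff": float(np.nanmean(chain_diff)),
                    })
                else:
                    single_rows.append({"chrom": chrom, "pos": int(chain_pos[0]),
                                        "direction": direction,
                                        "meth_diff": float(chain_diff[0])})
                start = i
    dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "n_dmcs",
                                           "direction", "size_bp", "mean_diff"])
    singles = pd.DataFrame(single_rows, columns=["chrom", "pos", "direction", "meth_diff"])
    if len(dmrs):
        dmrs = dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
    if len(singles):
        singles = singles.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return dmrs, singles


def dmr_summary(dmrs: pd.DataFrame, singletons: pd.DataFrame) -> dict:
    """Counts, mean sizes and DMCs-per-region statistics, by direction."""
    out = {}
    for direction in ("hypo", "hyper"):
        d = dmrs[dmrs["direction"] == direction]
        s = singletons[singletons["direction"] == direction]
        out[direction] = {
            "n_dmrs": len(d),
            "n_singletons": len(s),
            "mean_size_bp": float(d["size_bp"].mean()) if len(d) else np.nan,
            "mean_dmcs_per_region": float(d["n_dmcs"].mean()) if len(d) else np.nan,
            "max_dmcs_per_region": int(d["n_dmcs"].max()) if len(d) else 0,
        }
    return out


def annotate_sites(sites: pd.DataFrame, annotations: list[RegionSet],
                   precedence: dict[str, list[str]],
                   fallback: dict[str, str]) -> pd.DataFrame:
    """Assign each site one category per annotation family by precedence.

    ``annotations`` supplies one RegionSet per family (its name is the
    family); ``precedence[family]`` orders that family's categories from
    highest priority down; ``fallback[family]`` labels sites overlapping
    nothing (e.g. 'intergenic', 'open_sea').  Returns the site table with
    one extra column per family.
    """
    out = sites[["chrom", "pos"]].copy()
    for regs in annotations:
        fam = regs.name
        if fam not in precedence or fam not in fallback:
            raise ValueError(f"no precedence/fallback declared for family {fam!r}")
        order = {cat: r for r, cat in enumerate(precedence[fam])}
        unknown = set(regs.intervals["category"]) - set(order)
        if unknown:
            raise ValueError(f"family {fam!r}: categories with no precedence entry: "
                             f"{sorted(unknown)}")
        trees = regs.trees()
        labels = []
        for chrom, p in zip(out["chrom"], out["pos"]):
            tree = trees.get(str(chrom))
            hits = [iv.data for iv in tree[int(p)]] if tree is not None else []
            labels.append(min(hits, key=order.__getitem__) if hits else fallback[fam])
        out[fam] = labels
    return out


def annotation_counts(annotated: pd.DataFrame, family: str) -> pd.Series:
    return annotated[family].value_counts()


def enrichment_test(fg: tuple[int, int], bg: tuple[int, int]) -> dict:
    """Yates-corrected chi-square comparing a foreground proportion k/n to a
    background proportion K/N via the 2x2 table [[k, n-k], [K, N-K]].
    """
    k, n = fg
    K, N = bg
    if not (0 <= k <= n and 0 <= K <= N and n > 0 and N > 0):
        raise ValueError("need 0 <= k <= n and 0 <= K <= N with positive totals")
    table = np.array([[k, n - k], [K, N - K]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"chi2": np.nan, "p": np.nan, "direction": "undefined",
                "fg_prop": k / n, "bg_prop": K / N}
    chi2, p, _, _ = chi2_contingency(table, correction=True)
    direction = "enriched" if k / n > K / N else ("depleted" if k / n < K / N else "equal")
    return {"chi2": float(chi2), "p": float(p), "direction": direction,
            "fg_prop": k / n, "bg_prop": K / N}
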