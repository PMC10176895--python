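#!/usr/bin/env python
"""Region-level analysis of the called DMCs.

Merges each sex-stratified DMC list into DMRs (250-bp same-direction rule),
summarizes counts/sizes/DMCs-per-region, annotates DMCs against a synthetic
genic/CpG-context annotation, and tests dynamic-site enrichment with the
Yates chi-square.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import numpy as np
import pandas as pd

import methylseq_dm as md
from methylseq_dm.matrix import RegionSet
from methylseq_dm.regions import dmr_summary
from common import RESULTS, SCRATCH, SEED, cohort_paths


def _synthetic_annotation(sites: pd.DataFrame, rng) -> tuple[list, dict, dict]:
    """Interval sets standing in for genic/CpG-context annotation BEDs
    (synthetic: no genome sequence is consulted)."""
    fams = []
    for fam, cats in (("genic", ["promoter", "exon", "intron"]),
                      ("cpg", ["island", "shore", "shelf"])):
        rows = []
        for chrom, grp in sites.groupby("chrom"):
            lo, hi = int(grp.pos.min()), int(grp.pos.max()) + 1
            n_iv = max(3, len(grp) // 40)
            for _ in range(n_iv):
                a = int(rng.integers(lo, hi))
                rows.append((chrom, a, a + int(rng.integers(200, 3000)),
                             cats[int(rng.integers(0, 3))]))
        fams.append(RegionSet(fam, pd.DataFrame(
            rows, columns=["chrom", "start", "end", "category"])))
    precedence = {"genic": ["promoter", "exon", "intron"],
                  "cpg": ["island", "shore", "shelf"]}
    fallback = {"genic": "intergenic", "cpg": "open_sea"}
    return fams, precedence, fallback


def main() -> None:
    paths = cohort_paths()
    filt = md.MethylomeMatrix.read_tsv(paths["filtered"])
    rng = np.random.default_rng(SEED + 4)

    report = {}
    for name in ("males", "females", "combined"):
        dmcs = pd.read_csv(SCRATCH / f"dmc_{name}.tsv", sep="\t")
        dmrs, singles = md.merge_dmrs(dmcs, gap=250)
        dmrs.to_csv(SCRATCH / f"dmr_{name}.tsv", sep="\t", index=False)
        s = dmr_summary(dmrs, singles)
        report[name] = s
        print(f"{name}: {len(dmrs)} DMRs "
              f"({s['hypo']['n_dmrs']} hypo / {s['hyper']['n_dmrs']} hyper), "
              f"mean sizes {s['hypo']['mean_size_bp']}/{s['hyper']['mean_size_bp']} bp, "
              f"{s['hypo']['n_singletons'] + s['hyper']['n_singletons']} singletons")

    # annotation distributions, DMCs vs genome-wide background
    fams, precedence, fallback = _synthetic_annotation(filt.sites, rng)
    bg = md.annotate_sites(filt.sites, fams, precedence, fallback)
    dmcs = pd.read_csv(SCRATCH / "dmc_combined.tsv", sep="\t")
    fg = md.annotate_sites(dmcs[["chrom", "pos"]], fams, precedence, fallback)
    ann = {}
    for fam in ("genic", "cpg"):
        ann[fam] = {"dmc": fg[fam].value_counts().to_dict(),
                    "background": bg[fam].value_counts().to_dict()}
    pd.DataFrame(ann).to_json(RESULTS / "04_annotation_counts.json", indent=1)

    # dynamic-site enrichment: planted-effect sites stand in for the
    # environmentally sensitive subset of the capture panel
    truth = md.TruthSet.from_json(paths["truth"])
    full = md.MethylomeMatrix.read_tsv(paths["matrix"])
    dyn_keys = {(full.sites.chrom[s], full.sites.pos[s])
                for s in truth.true_dmc_sites}
    dmc_keys = set(zip(dmcs.chrom, dmcs.pos))
    bg_keys = set(zip(filt.sites.chrom, filt.sites.pos))
    k = len(dmc_keys & dyn_keys)
    K = len(bg_keys & dyn_keys)
    enr = md.enrichment_test((k, len(dmc_keys)), (K, len(bg_keys)))
    report["dynamic_site_enrichment"] = enr
    print(f"dynamic-site proportion: DMCs {k}/{len(dmc_keys)} vs background "
          f"{K}/{len(bg_keys)}; Yates chi2={enr['chi2']:.1f}, p={enr['p']:.2e} "
          f"({enr['direction']})")

    (RESULTS / "04_region_summary.json").write_text(
        json.dumps(report, indent=1, default=float))
    print(f"summary -> {RESULTS / '04_region_summary.json'}")


if __name__ == "__main__":
    main()
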