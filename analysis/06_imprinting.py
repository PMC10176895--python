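#!/usr/bin/env python
"""Imprinting-control-region analysis.

Per-CpG (group x sex) mean methylation within each imprinted block, two-way
ANOVA with Bonferroni-corrected within-sex contrasts, direction tallies
across blocks, capture-coverage accounting, and a per-CpG difference
bedGraph for browser-style viewing.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import numpy as np
import pandas as pd

import methylseq_dm as md
from common import ICR_BLOCKS, RESULTS, SCRATCH, cohort_paths


def main() -> None:
    paths = cohort_paths()
    filt = md.MethylomeMatrix.read_tsv(paths["filtered"])
    sheet = pd.read_csv(paths["samples"])

    # sensitivity pass: drop the samples the outlier screen (step 05) flagged,
    # since a globally shifted sample biases per-cell means at every block
    outlier_report = RESULTS / "05_outlier_report.json"
    excluded: list[str] = []
    if outlier_report.exists():
        excluded = json.loads(outlier_report.read_text())["all_sites"]["outliers"]
    if excluded:
        keep = [s for s in filt.samples if s not in excluded]
        filt = filt.take_samples(keep)
        sheet = sheet[~sheet["sample_id"].isin(excluded)]
        print(f"excluding detected outliers {excluded}")

    icrs = [md.ICRDefinition(b.name, b.chrom, b.start, b.end,
                             n_cpgs_total=max(4, (b.end - b.start) // 150))
            for b in ICR_BLOCKS]

    rows, bed_rows = [], []
    for icr in icrs:
        s = md.summarize_icr(filt, icr, sheet)
        if s.n_cpgs_captured < 2:
            print(f"{icr.name}: <2 CpGs captured, skipped")
            continue
        a = md.icr_anova(s)
        rows.append({
            "icr": icr.name, "n_cpgs": s.n_cpgs_captured,
            "coverage_fraction": round(s.coverage_fraction, 3),
            "diff_male": round(float(s.group_difference("M").mean()), 4),
            "diff_female": round(float(s.group_difference("F").mean()), 4),
            "p_group": a["p_group"], "p_sex": a["p_sex"],
            "p_interaction": a["p_interaction"],
            "p_male_bonf": a["p_male"], "p_female_bonf": a["p_female"],
        })
        for (chrom, pos), d in s.group_difference().items():
            bed_rows.append((chrom, pos, pos + 1, round(float(d), 4)))

    tab = pd.DataFrame(rows)
    tab.to_csv(RESULTS / "06_icr_anova.tsv", sep="\t", index=False)
    pd.DataFrame(bed_rows).to_csv(SCRATCH / "icr_diff.bedGraph", sep="\t",
                                  header=False, index=False)
    for r in rows:
        print(f"{r['icr']}: diff M {r['diff_male']:+.3f} (p {r['p_male_bonf']:.1e}), "
              f"F {r['diff_female']:+.3f} (p {r['p_female_bonf']:.1e}), "
              f"interaction p {r['p_interaction']:.1e}")

    tally = md.icr_direction_tally(filt, icrs, sheet)
    tally.to_csv(RESULTS / "06_icr_direction_tally.tsv", sep="\t", index=False)
    print(f"direction tally: {tally.attrs['n_hypo']} of "
          f"{tally.attrs['n_with_data']} blocks hypomethylated (combined); "
          f"female below male at {tally.attrs['n_female_below_male']}")

    cov = md.icr_coverage(icrs, filt.sites)
    cov.to_csv(RESULTS / "06_icr_coverage.tsv", sep="\t", index=False)
    (RESULTS / "06_icr_tallies.json").write_text(json.dumps(
        {k: int(v) for k, v in tally.attrs.items()}, indent=1))
    print(f"tables -> {RESULTS}/06_icr_*.tsv")


if __name__ == "__main__":
    main()
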