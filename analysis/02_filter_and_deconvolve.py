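#!/usr/bin/env python
"""Apply the site-retention funnel and estimate cell composition.

Reports the funnel counts (coverage window -> minimum-sample rule ->
sex-chromosome drop), the coverage CDF, and NNLS cell-proportion estimates
for every sample.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import methylseq_dm as md
from common import RESULTS, cohort_paths


def main() -> None:
    paths = cohort_paths()
    matrix = md.MethylomeMatrix.read_tsv(paths["matrix"])
    funnel = {"input_sites": matrix.n_sites}

    filt = md.apply_coverage_filter(matrix, md.FilterConfig())
    funnel["after_coverage_and_min30_and_autosomes"] = filt.n_sites
    filt.write_tsv(paths["filtered"])

    cdf = md.coverage_cdf(filt)
    cdf.to_csv(RESULTS / "02_coverage_cdf.tsv", sep="\t", index=False)

    panel = md.ReferencePanel.from_tsv(paths["panel"])
    props = md.deconvolve(filt, panel)
    props.to_csv(paths["proportions"])
    summary = props[panel.cell_types].describe().loc[["mean", "std", "min", "max"]]
    summary.to_csv(RESULTS / "02_cell_proportion_summary.tsv", sep="\t")

    (RESULTS / "02_funnel.json").write_text(json.dumps(funnel, indent=1))
    print(f"funnel: {funnel}")
    print("mean estimated proportions:",
          {c: round(float(props[c].mean()), 3) for c in panel.cell_types})
    print(f"per-sample proportions -> {paths['proportions']}")


if __name__ == "__main__":
    main()
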