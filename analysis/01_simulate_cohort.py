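#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes the count matrix, sample sheet, reference panel, imprinted-block BED
and ground truth to scratch/, and a cohort overview table to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import methylseq_dm as md
from common import RESULTS, cohort_paths, study_config


def main() -> None:
    cfg = study_config()
    paths = cohort_paths()
    panel = md.simulate_reference_panel(cfg)
    matrix, sheet, truth = md.simulate_cohort(cfg, panel)

    matrix.write_tsv(paths["matrix"])
    sheet.to_csv(paths["samples"], index=False)
    panel.to_tsv(paths["panel"])
    truth.to_json(paths["truth"])
    from methylseq_dm.simulate import icr_region_set
    icr_region_set(cfg).to_bed(paths["icrs"])

    scopes = {}
    for e in cfg.planted_effects:
        scopes[e.scope] = scopes.get(e.scope, 0) + 1
    overview = {
        "n_control": cfg.n_control, "n_case": cfg.n_case,
        "n_cpgs": matrix.n_sites,
        "n_panel_markers": len(panel.cpgs),
        "planted_effects_by_scope": scopes,
        "n_icr_blocks": len(cfg.icr_blocks),
        "true_outliers": truth.true_outlier_ids,
        "sex_counts": sheet.groupby(["group", "sex"]).size().to_dict().__str__(),
    }
    out = RESULTS / "01_cohort_overview.json"
    out.write_text(json.dumps(overview, indent=1))
    print(f"simulated {matrix.n_sites} CpGs x {matrix.n_samples} samples; "
          f"{len(cfg.planted_effects)} planted effects ({scopes}); "
          f"outliers {truth.true_outlier_ids}")
    print(f"overview -> {out}")


if __name__ == "__main__":
    main()
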