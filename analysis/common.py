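"""Shared study conditions for the numbered analysis drivers.

One synthetic cohort emulating the cord-blood study structure: 36 control +
37 case samples of both sexes, 20,000 CpGs (a desk-scale stand-in for the
~2.4M-site capture panel), a 7-cell-type marker panel, planted group
effects that are shared, sex-specific or opposite-direction between the
sexes, six half-methylated imprinted blocks with small group-by-sex shifts,
and two globally shifted outlier samples.  Bulky intermediates go to
scratch/, summary tables to results/.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import methylseq_dm as md

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20230511

# six ICR blocks in the style of the loci the study examines in detail:
# maternal KCNQ1OT1 and the GNAS cluster, paternal H19/IGF2; female-biased
# hypomethylation with male hypermethylation at the two headline loci
ICR_BLOCKS = [
    md.ICRBlock("KCNQ1OT1", "chr11", 2_720_000, 2_723_000,
                shift_male=0.15, shift_female=-0.15),
    md.ICRBlock("H19_IGF2", "chr11", 2_019_000, 2_022_000,
                shift_male=0.10, shift_female=-0.12),
    md.ICRBlock("GNAS_NESP", "chr20", 57_414_000, 57_416_000,
                shift_male=0.10, shift_female=-0.10),
    md.ICRBlock("GNAS_AS1", "chr20", 57_423_000, 57_425_000),
    md.ICRBlock("GNAS_XL", "chr20", 57_428_000, 57_430_000,
                shift_male=-0.08, shift_female=-0.10),
    md.ICRBlock("GNAS_AB", "chr20", 57_463_000, 57_465_000,
                shift_male=0.0, shift_female=-0.10),
]


def study_config() -> md.SimulationConfig:
    rng = np.random.default_rng(SEED)
    scopes = ["both", "male_only", "female_only", "opposite"]
    weights = [0.1, 0.35, 0.4, 0.15]  # mostly sex-specific, female excess
    # ~90 clusters of 2-5 neighbouring affected CpGs (DMR material, one sign
    # and scope per cluster) plus ~300 isolated sites
    effects: list[md.PlantedEffect] = []
    used: set[int] = set()
    starts = rng.choice(17_000, 90, replace=False)
    for s in starts:
        length = int(rng.integers(2, 6))
        sign = float(rng.choice([-1.0, 1.0]))
        scope = str(rng.choice(scopes, p=weights))
        for k in range(length):
            if s + k not in used:
                effects.append(md.PlantedEffect(int(s + k),
                                                sign * float(rng.uniform(0.8, 1.8)),
                                                scope))
                used.add(int(s + k))
    for s in rng.choice(18_000, 400, replace=False):
        if len(used) >= 600:
            break
        if int(s) not in used:
            effects.append(md.PlantedEffect(
                int(s), float(rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.8)),
                str(rng.choice(scopes, p=weights))))
            used.add(int(s))
    # missingness calibrated so roughly a third of retained sites are
    # complete-case across all 73 samples, as in deep capture data
    return md.SimulationConfig(
        n_cpgs=20_000, seed=SEED, planted_effects=effects,
        icr_blocks=ICR_BLOCKS, n_outliers=2, outlier_shift=3.0,
        outlier_site_frac=0.4, frac_sex_chrom=0.02,
        dispersion_rho=0.0, missing_rate=0.005, coverage_log_sd=0.6)


def cohort_paths() -> dict[str, Path]:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return {
        "matrix": SCRATCH / "matrix.tsv",
        "filtered": SCRATCH / "filtered.tsv",
        "samples": SCRATCH / "samples.csv",
        "panel": SCRATCH / "panel.tsv",
        "truth": SCRATCH / "truth.json",
        "icrs": SCRATCH / "icrs.bed",
        "proportions": SCRATCH / "proportions.csv",
    }
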