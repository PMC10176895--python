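import numpy as np
import pandas as pd
import pytest

import methylseq_dm as md


@pytest.fixture(scope="session")
def small_cohort():
    """2000-CpG, 10+10-sample cohort with planted effects of every scope,
    one imprinted block and one outlier sample."""
    rng = np.random.default_rng(11)
    scopes = ["both", "male_only", "female_only", "opposite"]
    effects = [md.PlantedEffect(int(s), float(rng.choice([-1.5, 1.5])), scopes[i % 4])
               for i, s in enumerate(rng.choice(1500, 40, replace=False))]
    blocks = [md.ICRBlock("KCNQ1OT1", "chr11", 2_720_000, 2_722_000,
                          shift_male=0.2, shift_female=-0.2)]
    cfg = md.SimulationConfig(n_cpgs=2000, n_control=10, n_case=10, seed=11,
                              planted_effects=effects, icr_blocks=blocks,
                              n_outliers=1, outlier_shift=3.0,
                              frac_sex_chrom=0.02, missing_rate=0.05)
    panel = md.simulate_reference_panel(cfg)
    matrix, sheet, truth = md.simulate_cohort(cfg, panel)
    return {"config": cfg, "panel": panel, "matrix": matrix,
            "sheet": sheet, "truth": truth}


@pytest.fixture(scope="session")
def filtered(small_cohort):
    cfg = md.FilterConfig(min_samples=15)
    return md.apply_coverage_filter(small_cohort["matrix"], cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-built 4-site x 3-sample matrix with one missing cell."""
    sites = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1", "chr2"],
                          "pos": [99, 199, 460, 99]})
    m = np.array([[5, 0, 17], [3, 10, 2], [50, 40, 30], [1, 2, 3]])
    t = np.array([[10, 20, 17], [30, 20, 25], [100, 80, 60], [10, 10, 10]])
    mask = np.zeros((4, 3), dtype=bool)
    mask[1, 2] = True
    return md.MethylomeMatrix(sites, ["a", "b", "c"], m, t, mask)
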