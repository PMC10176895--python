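"""Published summary inputs of the motivating cord-blood study.

The cohort-description tables of an ART/hypofertility cord-blood methylome
study are printed as group counts and mean (SD) summaries; the raw data are
controlled-access.  These printed values are *inputs*: the statistics
reported alongside them (Fisher exact, chi-square, unpaired t) can be
recomputed from them directly, as can the headline arithmetic relating the
sex-stratified DMC totals.
"""

from __future__ import annotations

from .cohort_stats import GroupSummary

# Cohort description, control (n=36) vs ART/hypofertile (n=37).
# Categorical rows: counts per group.
INFANT_SEX_TABLE = [[17, 19], [19, 18]]            # M/F by group; reported p 0.82
DELIVERY_ROUTE_TABLE = [[26, 10], [23, 14]]        # vaginal/C-section; reported p 0.46
SMOKING_TABLE = [[3, 7, 26], [3, 5, 29]]           # S/SSP/NS; reported p 0.79
# Numeric rows: mean (SD) with per-variable complete-case n (footnoted
# missing values: 1 control and 5 case BMI unknown; 1 case paternal age).
MATERNAL_AGE = (GroupSummary(34.1, 3.3, 36), GroupSummary(33.8, 4.5, 37))   # reported 0.70
PATERNAL_AGE = (GroupSummary(36.7, 5.3, 36), GroupSummary(37.7, 7.1, 36))   # reported 0.48
MATERNAL_BMI = (GroupSummary(24.5, 5.0, 35), GroupSummary(24.8, 5.1, 32))   # reported 0.81
GESTATIONAL_AGE = (GroupSummary(38.7, 1.6, 36), GroupSummary(38.6, 1.6, 37))  # reported 0.79

# Subgroup description, in vivo (n=17) vs in vitro (n=20).
SUBGROUP_INFANT_SEX_TABLE = [[10, 7], [9, 11]]     # M/F; reported p 0.51

# Genome-wide DMC totals from the combined and sex-stratified analyses.
DMC_TOTAL_COMBINED = 3352
DMC_TOTAL_MALE = 2691
DMC_TOTAL_FEMALE = 3933


def female_vs_male_dmc_excess_pct(n_female: int = DMC_TOTAL_FEMALE,
                                  n_male: int = DMC_TOTAL_MALE) -> float:
    """Percent excess of female over male DMC totals ((F - M) / M * 100)."""
    return 100.0 * (n_female - n_male) / n_male
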