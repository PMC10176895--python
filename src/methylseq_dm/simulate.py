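"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a two-group cord-blood capture-bisulfite
study: ~36 control vs ~37 case samples of both sexes, per-site read depths
following a discretised log-normal clipped to [1, 600] (so the 15x/500x
coverage window is exercised on both tails), 7-cell-type Dirichlet mixtures
over a marker reference panel, planted group effects on the logit scale that
may be shared, sex-specific, or opposite-direction between the sexes,
half-methylated imprinted blocks with small group-by-sex shifts, and a few
globally shifted outlier samples.  Counts are beta-binomial with intra-class
correlation ``dispersion_rho``; rho=0 recovers the binomial analysis model
exactly, which is what the type-I-error checks rely on.

Everything planted is recorded in a :class:`TruthSet` so downstream recovery
can be scored without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import MethylomeMatrix, RegionSet
from .deconvolution import ReferencePanel

CELL_TYPES_CORD_BLOOD = (
    "Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK", "nRBC",
)


@dataclass
class PlantedEffect:
    """A group effect at one CpG, on the logit scale.

    scope: 'both' applies to cases of both sexes; 'male_only'/'female_only'
    restrict it; 'opposite' applies +effect to case males and -effect to
    case females.
    """

    site: int
    effect: float
    scope: str = "both"

    def __post_init__(self) -> None:
        if self.scope not in ("both", "male_only", "female_only", "opposite"):
            raise ValueError(f"unknown effect scope {self.scope!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")

    def sex_effects(self) -> tuple[float, float]:
        """(male, female) logit shifts applied to the case group."""
        if self.scope == "both":
            return self.effect, self.effect
        if self.scope == "male_only":
            return self.effect, 0.0
        if self.scope == "female_only":
            return 0.0, self.effect
        return self.effect, -self.effect  # opposite


@dataclass
class ICRBlock:
    """Imprinted block: ~50%-methylated interval with a small group x sex shift."""

    name: str
    chrom: str
    start: int
    end: int
    baseline: float = 0.5
    shift_male: float = 0.0    # logit shift in case males
    shift_female: float = 0.0  # logit shift in case females


@dataclass
class SimulationConfig:
    n_control: int = 36
    n_case: int = 37
    sex_ratio: float = 0.5          # fraction male, per group
    n_cpgs: int = 20_000
    n_cell_types: int = 7
    dirichlet_alpha: tuple[float, ...] | None = None
    coverage_log_mean: float = 4.1  # median ~60x
    coverage_log_sd: float = 0.8
    coverage_floor: int = 1
    coverage_cap: int = 600
    missing_rate: float = 0.05
    dispersion_rho: float = 0.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    icr_blocks: list[ICRBlock] = field(default_factory=list)
    n_outliers: int = 0
    outlier_shift: float = 0.0      # logit-scale global shift
    outlier_site_frac: float = 0.3
    # planted-effect sites draw baselines within this range so a given logit
    # effect produces at least the intended beta shift (None = no constraint)
    planted_baseline_range: tuple[float, float] | None = (0.15, 0.85)
    frac_sex_chrom: float = 0.0     # fraction of CpGs placed on chrX
    markers_per_type: int = 50
    marker_margin: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_case, self.n_cpgs) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio in [0,1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate in [0,1)")
        if not 0 <= self.dispersion_rho < 1:
            raise ValueError("dispersion_rho in [0,1)")
        n = self.n_control + self.n_case
        if self.n_outliers > 0.1 * n:
            raise ValueError("outlier samples must be <= 10% of the cohort")
        if self.dirichlet_alpha is None:
            # Granulocyte-dominated cord-blood-like composition.
            base = (4.0, 12.0, 8.0, 40.0, 6.0, 4.0, 6.0)
            self.dirichlet_alpha = base[: self.n_cell_types] if self.n_cell_types <= 7 \
                else base + (4.0,) * (self.n_cell_types - 7)
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must equal n_cell_types")
        for eff in self.planted_effects:
            if not 0 <= eff.site < self.n_cpgs:
                raise ValueError(f"planted site {eff.site} out of range")


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort, for recovery scoring."""

    true_dmc_sites: dict[int, tuple[float, float]]   # site -> (male, female) logit effect
    true_proportions: pd.DataFrame                    # sample x cell type
    true_outlier_ids: list[str]
    true_icr_shifts: dict[str, tuple[float, float]]  # block -> (male, female) shift

    def __post_init__(self) -> None:
        p = self.true_proportions.to_numpy()
        if (p < 0).any() or np.abs(p.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("true proportions must be nonnegative and sum to 1")

    def to_json(self, path) -> None:
        obj = {
            "true_dmc_sites": {str(k): list(v) for k, v in self.true_dmc_sites.items()},
            "true_proportions": {
                "index": list(self.true_proportions.index),
                "columns": list(self.true_proportions.columns),
                "values": self.true_proportions.to_numpy().tolist(),
            },
            "true_outlier_ids": self.true_outlier_ids,
            "true_icr_shifts": {k: list(v) for k, v in self.true_icr_shifts.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            obj = json.load(fh)
        props = pd.DataFrame(obj["true_proportions"]["values"],
                             index=obj["true_proportions"]["index"],
                             columns=obj["true_proportions"]["columns"])
        return cls(
            {int(k): tuple(v) for k, v in obj["true_dmc_sites"].items()},
            props,
            list(obj["true_outlier_ids"]),
            {k: tuple(v) for k, v in obj["true_icr_shifts"].items()},
        )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def simulate_reference_panel(config: SimulationConfig,
                             markers_per_type: int | None = None,
                             margin: float | None = None) -> ReferencePanel:
    """Marker-CpG reference panel: per cell type, ``markers_per_type`` CpGs whose
    methylation differs from every other type by at least ``margin``.

    Panel CpGs live on a dedicated coordinate block (chr20:2,000,000+) so the
    cohort generator can embed them verbatim into its site list.
    """
    k = config.n_cell_types
    if k < 2:
        raise ValueError("need at least 2 cell types")
    mk = config.markers_per_type if markers_per_type is None else markers_per_type
    mg = config.marker_margin if margin is None else margin
    if not 0 < mg <= 0.9:
        raise ValueError("marker margin must be in (0, 0.9] to fit within [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    cell_types = list(CELL_TYPES_CORD_BLOOD[:k]) if k <= 7 else \
        list(CELL_TYPES_CORD_BLOOD) + [f"CT{i}" for i in range(8, k + 1)]
    n = k * mk
    lo_hi_gap = mg
    # owner high / others low, alternating direction per marker for realism
    profile = np.empty((n, k))
    for c in range(k):
        for j in range(mk):
            i = c * mk + j
            hyper = (j % 2 == 0)
            others = rng.uniform(0.02, (1 - lo_hi_gap) - 0.08, size=k)
            owner = rng.uniform(others.max() + lo_hi_gap, 0.98)
            row = others
            row[c] = owner
            if not hyper:  # owner hypomethylated instead
                row = 1.0 - row
            profile[i] = row
    pos = 2_000_000 + 100 * np.arange(n)
    cpgs = pd.DataFrame({"chrom": "chr20", "pos": pos})
    panel = ReferencePanel(cpgs, cell_types, profile)
    span = profile.max(axis=1) - profile.min(axis=1)
    if (span < mg).any():
        raise AssertionError("panel construction violated the marker margin")
    return panel


def _site_table(config: SimulationConfig, panel: ReferencePanel,
                rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Site coordinates: panel CpGs embedded + random CpGs over autosomes (+chrX).

    Returns (sites, panel_row_of_site or -1, icr_block_index or -1).
    """
    n_panel = len(panel.cpgs)
    n_rand = config.n_cpgs - n_panel
    if n_rand < 0:
        raise ValueError("n_cpgs smaller than the reference panel")
    n_icr_sites = 0
    icr_rows = []
    for b, blk in enumerate(config.icr_blocks):
        span = blk.end - blk.start
        n_b = max(4, span // 150)  # CpG every ~150 bp, dense imprinted block
        ps = np.sort(rng.choice(np.arange(blk.start, blk.end), size=min(n_b, span), replace=False))
        for p in ps:
            icr_rows.append((blk.chrom, int(p), b))
        n_icr_sites += len(ps)
    n_free = n_rand - n_icr_sites
    if n_free < 0:
        raise ValueError("n_cpgs too small for the requested imprinted blocks")
    n_x = int(round(config.frac_sex_chrom * n_free))
    chroms, positions = [], []
    autos = [f"chr{i}" for i in range(1, 23)]
    per = np.full(len(autos), (n_free - n_x) // len(autos))
    per[: (n_free - n_x) - per.sum()] += 1
    def _cpg_gaps(count: int) -> np.ndarray:
        # island-like clustering: mostly short inter-CpG gaps, occasional jumps
        short = rng.integers(10, 200, size=count)
        long_ = rng.integers(300, 5000, size=count)
        return np.where(rng.random(count) < 0.7, short, long_)

    for chrom, cnt in zip(autos, per):
        pos = 1_000_000 + np.cumsum(_cpg_gaps(cnt))
        chroms += [chrom] * cnt
        positions += pos.tolist()
    if n_x:
        chroms += ["chrX"] * n_x
        positions += (1_000_000 + np.cumsum(_cpg_gaps(n_x))).tolist()
    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    df["panel_row"] = -1
    df["icr_block"] = -1
    pan = panel.cpgs.copy()
    pan["panel_row"] = np.arange(n_panel)
    pan["icr_block"] = -1
    icr_df = pd.DataFrame(icr_rows, columns=["chrom", "pos", "icr_block"]) if icr_rows \
        else pd.DataFrame(columns=["chrom", "pos", "icr_block"])
    icr_df["panel_row"] = -1
    allsites = pd.concat([df, pan, icr_df[["chrom", "pos", "panel_row", "icr_block"]]],
                         ignore_index=True)
    allsites = allsites.drop_duplicates(["chrom", "pos"])
    # lexicographic chromosome order (the `sort -k1,1 -k2,2n` BED convention)
    allsites = allsites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    sites = allsites[["chrom", "pos"]].copy()
    sites["pos"] = sites["pos"].astype(np.int64)
    return sites, allsites["panel_row"].to_numpy(), allsites["icr_block"].to_numpy()


def simulate_cohort(config: SimulationConfig, panel: ReferencePanel,
                    ) -> tuple[MethylomeMatrix, pd.DataFrame, TruthSet]:
    """Generate (MethylomeMatrix, sample sheet, TruthSet) for one cohort.

    The sample sheet has columns sample_id, group (control/case), subgroup
    (control / in_vivo / in_vitro), sex (M/F), complications (0/1) and a
    numeric maternal_age column, mirroring the metadata the analysis consumes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = config.n_control + config.n_case
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["control"] * config.n_control + ["case"] * config.n_case)

    def _sexes(count: int) -> np.ndarray:
        n_m = int(round(config.sex_ratio * count))
        sex = np.array(["M"] * n_m + ["F"] * (count - n_m))
        return rng.permutation(sex)

    sex = np.concatenate([_sexes(config.n_control), _sexes(config.n_case)])
    # case subgroup split ~ 17 in vivo / 20 in vitro of 37
    n_vivo = int(round(config.n_case * 17 / 37))
    sub_case = rng.permutation(np.array(["in_vivo"] * n_vivo +
                                        ["in_vitro"] * (config.n_case - n_vivo)))
    subgroup = np.concatenate([np.array(["control"] * config.n_control), sub_case])
    complications = (rng.random(n) < 0.29).astype(int)
    maternal_age = np.round(rng.normal(34.0, 4.0, size=n), 1)

    sheet = pd.DataFrame({
        "sample_id": sample_ids, "group": group, "subgroup": subgroup,
        "sex": sex, "complications": complications, "maternal_age": maternal_age,
    })

    sites, panel_row, icr_block = _site_table(config, panel, rng)
    n_sites = len(sites)

    # per-sample mixing proportions
    props = rng.dirichlet(config.dirichlet_alpha, size=n)
    props_df = pd.DataFrame(props, index=sample_ids, columns=panel.cell_types)

    # cell-type baseline betas per site
    is_marker = panel_row >= 0
    is_icr = icr_block >= 0
    base = np.empty(n_sites)
    kind = rng.random(n_sites)
    # genome-like bimodal background: mostly methylated, CpG-island-like low tail
    base = np.where(kind < 0.6, rng.beta(8, 2, n_sites),
                    np.where(kind < 0.9, rng.beta(2, 8, n_sites), rng.beta(2, 2, n_sites)))
    base = np.clip(base, 0.02, 0.98)
    if config.planted_effects and config.planted_baseline_range is not None:
        lo, hi = config.planted_baseline_range
        planted_idx = np.array([e.site for e in config.planted_effects])
        base[planted_idx] = np.clip(base[planted_idx], lo, hi)
    base[is_icr] = np.array([config.icr_blocks[b].baseline for b in icr_block[is_icr]])
    # expected beta before shifts: markers mix the panel, others are shared
    mu = np.repeat(base[:, None], n, axis=1)
    if is_marker.any():
        mu[is_marker] = panel.profile[panel_row[is_marker]] @ props.T

    # logit-scale shifts
    eta = _logit(np.clip(mu, 1e-6, 1 - 1e-6))
    is_case = group == "case"
    is_male = sex == "M"
    truth_effects: dict[int, tuple[float, float]] = {}
    for eff in config.planted_effects:
        em, ef = eff.sex_effects()
        eta[eff.site, is_case & is_male] += em
        eta[eff.site, is_case & ~is_male] += ef
        truth_effects[eff.site] = (em, ef)
    icr_truth: dict[str, tuple[float, float]] = {}
    for b, blk in enumerate(config.icr_blocks):
        rows = icr_block == b
        eta[np.ix_(rows, is_case & is_male)] += blk.shift_male
        eta[np.ix_(rows, is_case & ~is_male)] += blk.shift_female
        icr_truth[blk.name] = (blk.shift_male, blk.shift_female)

    outlier_ids: list[str] = []
    if config.n_outliers:
        picks = rng.choice(n, size=config.n_outliers, replace=False)
        outlier_ids = [sample_ids[i] for i in sorted(picks)]
        n_shift = int(round(config.outlier_site_frac * n_sites))
        shifted = rng.choice(n_sites, size=n_shift, replace=False)
        for i in picks:
            eta[shifted, i] += config.outlier_shift

    p_true = _logistic(eta)

    # read depths and counts
    t = np.rint(np.exp(rng.normal(config.coverage_log_mean, config.coverage_log_sd,
                                  size=(n_sites, n)))).astype(np.int64)
    t = np.clip(t, config.coverage_floor, config.coverage_cap)
    if config.dispersion_rho > 0:
        rho = config.dispersion_rho
        conc = (1 - rho) / rho
        p_draw = rng.beta(np.clip(p_true * conc, 1e-8, None),
                          np.clip((1 - p_true) * conc, 1e-8, None))
    else:
        p_draw = p_true
    m = rng.binomial(t, p_draw)
    mask = rng.random((n_sites, n)) < config.missing_rate

    matrix = MethylomeMatrix(sites, sample_ids, m, t, mask, validate=False)
    truth = TruthSet(truth_effects, props_df, outlier_ids, icr_truth)
    return matrix, sheet, truth


def icr_region_set(config: SimulationConfig) -> RegionSet:
    """BED-style RegionSet of the configured imprinted blocks."""
    rows = [(b.chrom, b.start, b.end, b.name) for b in config.icr_blocks]
    return RegionSet("icr", pd.DataFrame(rows, columns=["chrom", "start", "end", "category"]))
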