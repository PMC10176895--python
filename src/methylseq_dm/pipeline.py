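"""End-to-end pipeline: filter -> deconvolve -> DMC designs -> DMRs ->
annotation -> outliers -> ICRs -> cohort statistics, with a run manifest.

All randomness funnels through a single seed; rerunning with the same
config and inputs is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import cohort_table
from .deconvolution import ReferencePanel, deconvolve
from .dmc import DesignSpec, call_dmcs, compare_dmc_sets
from .imprinting import ICRDefinition, icr_anova, icr_direction_tally, summarize_icr
from .matrix import FilterConfig, MethylomeMatrix, RegionSet, apply_coverage_filter, \
    apply_site_exclusions
from .outliers import detect_outliers, outlier_enrichment
from .regions import dmr_summary, merge_dmrs

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_path: str
    samples_path: str
    panel_path: str | None = None
    exclusion_beds: list[str] = field(default_factory=list)
    icr_bed: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    designs: list[DesignSpec] = field(default_factory=lambda: [
        DesignSpec(covariates=("sex", "cells")),
        DesignSpec(covariates=("cells",), sample_subset="males"),
        DesignSpec(covariates=("cells",), sample_subset="females"),
    ])
    dmr_gap: int = 250
    q_threshold: float = 0.05
    outlier_penalty: float | str = "mbic"
    min_panel_frac: float = 0.9
    seed: int = 0
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        designs = [DesignSpec(**{**d, "covariates": tuple(d.get("covariates", ("sex",)))})
                   for d in raw.pop("designs", [])]
        cfg = cls(filter=filt, **raw)
        if designs:
            cfg.designs = designs
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in the published order; returns the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    bundle: dict = {"manifest": manifest}

    matrix = MethylomeMatrix.read_tsv(config.matrix_path)
    sheet = pd.read_csv(config.samples_path)
    manifest["stages"]["input"] = {"n_sites": matrix.n_sites,
                                   "n_samples": matrix.n_samples}

    exclusions = [RegionSet.from_bed(p, name=Path(p).stem) for p in config.exclusion_beds]
    matrix = apply_site_exclusions(matrix, exclusions)
    manifest["stages"]["exclusions"] = {"n_sites": matrix.n_sites}
    matrix = apply_coverage_filter(matrix, config.filter)
    manifest["stages"]["coverage_filter"] = {"n_sites": matrix.n_sites}
    bundle["matrix"] = matrix

    proportions = None
    if config.panel_path:
        panel = ReferencePanel.from_tsv(config.panel_path)
        proportions = deconvolve(matrix, panel, min_frac=config.min_panel_frac)
        proportions.to_csv(out / "cell_proportions.csv")
        manifest["stages"]["deconvolution"] = {"n_samples": len(proportions)}
    bundle["proportions"] = proportions

    dmc_results = {}
    for design in config.designs:
        res = call_dmcs(matrix, sheet, design, q_threshold=config.q_threshold,
                        proportions=proportions)
        res.results.to_csv(out / f"dmc_{design.name}_full.tsv", sep="\t", index=False)
        res.dmcs.to_csv(out / f"dmc_{design.name}.tsv", sep="\t", index=False)
        dmrs, singles = merge_dmrs(res.dmcs, gap=config.dmr_gap)
        dmrs.to_csv(out / f"dmr_{design.name}.tsv", sep="\t", index=False)
        dmc_results[design.name] = {"dmc": res, "dmrs": dmrs, "singletons": singles}
        manifest["stages"][f"dmc_{design.name}"] = {
            **res.summary(), "dmr": dmr_summary(dmrs, singles)}
    bundle["dmc"] = dmc_results

    icr_sites = None
    icrs: list[ICRDefinition] = []
    if config.icr_bed:
        regs = RegionSet.from_bed(config.icr_bed, name="icr")
        icrs = [ICRDefinition(name=str(r.category), chrom=str(r.chrom),
                              start=int(r.start), end=int(r.end))
                for r in regs.intervals.itertuples()]
        trees = regs.trees()
        hit = np.zeros(matrix.n_sites, dtype=bool)
        for i, (c, p) in enumerate(zip(matrix.sites["chrom"], matrix.sites["pos"])):
            t = trees.get(str(c))
            hit[i] = t is not None and t.overlaps_point(int(p))
        icr_sites = np.flatnonzero(hit)

    outlier_runs = {}
    for tag, subset in (("all_sites", None), ("icr_sites", icr_sites)):
        if tag == "icr_sites" and icr_sites is None:
            continue
        try:
            rep = detect_outliers(matrix, penalty=config.outlier_penalty,
                                  site_subset=subset)
        except ValueError as exc:  # e.g. no complete-case sites in the subset
            manifest["stages"][f"outliers_{tag}"] = {"skipped": str(exc)}
            continue
        enrich = {f: outlier_enrichment(rep.outlier_ids, sheet, factor=f)
                  for f in ("group", "sex")}
        outlier_runs[tag] = {"report": rep, "enrichment": enrich}
        manifest["stages"][f"outliers_{tag}"] = {
            "n_outliers": len(rep.outlier_ids), "outliers": rep.outlier_ids,
            "enrichment_p": {f: e["p"] for f, e in enrich.items()}}
    bundle["outliers"] = outlier_runs

    if icrs:
        tally = icr_direction_tally(matrix, icrs, sheet)
        tally.to_csv(out / "icr_direction_tally.tsv", sep="\t", index=False)
        anovas = {}
        for icr in icrs:
            s = summarize_icr(matrix, icr, sheet)
            if s.n_cpgs_captured >= 2:
                try:
                    anovas[icr.name] = icr_anova(s)
                except ValueError:
                    continue
        bundle["icr"] = {"tally": tally, "anova": anovas}
        manifest["stages"]["icr"] = {"n_with_data": int(tally.attrs.get("n_with_data", 0))}

    numeric = [c for c in ("maternal_age",) if c in sheet.columns]
    categorical = [c for c in ("sex", "complications") if c in sheet.columns]
    stats_tab = cohort_table(sheet, "group", numeric=numeric, categorical=categorical)
    stats_tab.to_csv(out / "cohort_table.csv", index=False)
    bundle["cohort_table"] = stats_tab
    manifest["stages"]["cohort_stats"] = {"n_rows": len(stats_tab)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return bundle


def make_report(bundle: dict) -> dict:
    """Tabular summary of a completed bundle: DMC/DMR counts, diff bins,
    pairwise overlap/concordance, outlier decisions, ICR tallies."""
    report: dict = {"designs": {}, "comparisons": {}, "outliers": {}, "icr": {}}
    dmc = bundle.get("dmc", {})
    for name, res in dmc.items():
        report["designs"][name] = {**res["dmc"].summary(),
                                   "dmr": dmr_summary(res["dmrs"], res["singletons"])}
    names = list(dmc)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            report["comparisons"][f"{a}|{b}"] = compare_dmc_sets(
                dmc[a]["dmc"].dmcs, dmc[b]["dmc"].dmcs)
    for tag, run in bundle.get("outliers", {}).items():
        rep = run["report"]
        report["outliers"][tag] = {"outlier_ids": rep.outlier_ids, "side": rep.side,
                                   "enrichment_p": {f: e["p"] for f, e in
                                                    run["enrichment"].items()}}
    if "icr" in bundle:
        tally = bundle["icr"]["tally"]
        report["icr"] = {k: tally.attrs.get(k) for k in
                         ("n_with_data", "n_hypo", "n_hyper", "n_female_below_male")}
    return report
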