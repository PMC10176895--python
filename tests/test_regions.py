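"""DMR merging (against a brute-force chain oracle), annotation, enrichment."""

import numpy as np
import pandas as pd
import pytest

import methylseq_dm as md
from methylseq_dm.matrix import RegionSet
from methylseq_dm.regions import dmr_summary


def _chain_oracle(positions, gap):
    """Independent chain construction: quadratic scan over sorted positions."""
    chains, cur = [], [positions[0]]
    for p in positions[1:]:
        if p - cur[-1] <= gap:
            cur.append(p)
        else:
            chains.append(cur)
            cur = [p]
    chains.append(cur)
    return chains


def _dmc_frame(chrom, pos, direction, diffs=None):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "direction": direction,
                         "meth_diff": diffs if diffs is not None
                         else [0.1 if d == "hyper" else -0.1 for d in direction]})


class TestMergeDmrs:
    def test_forced_example_100_300_600(self):
        dmcs = _dmc_frame("chr1", [100, 300, 600], ["hypo"] * 3)
        dmrs, singles = md.merge_dmrs(dmcs, gap=250)
        assert len(dmrs) == 1 and len(singles) == 1
        r = dmrs.iloc[0]
        assert (r.start, r.end, r.n_dmcs, r.size_bp) == (100, 300, 2, 202)
        assert singles.iloc[0].pos == 600

    def test_opposite_directions_never_merge(self):
        dmcs = _dmc_frame("chr1", [100, 150], ["hypo", "hyper"])
        dmrs, singles = md.merge_dmrs(dmcs)
        assert len(dmrs) == 0 and len(singles) == 2

    def test_gap_boundary_inclusive(self):
        dmcs = _dmc_frame("chr1", [0, 250], ["hyper", "hyper"])
        dmrs, _ = md.merge_dmrs(dmcs, gap=250)
        assert len(dmrs) == 1
        dmrs2, _ = md.merge_dmrs(_dmc_frame("chr1", [0, 251], ["hyper"] * 2), gap=250)
        assert len(dmrs2) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_chain_oracle_on_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        n = 1000
        chroms = np.sort(rng.choice(["chr1", "chr2", "chr3"], n))
        pos = np.concatenate([np.sort(rng.choice(200_000, (chroms == c).sum(),
                                                 replace=False))
                              for c in ["chr1", "chr2", "chr3"]])
        direction = rng.choice(["hypo", "hyper"], n)
        dmcs = _dmc_frame(chroms, pos, direction)
        dmrs, singles = md.merge_dmrs(dmcs, gap=250)
        # conservation: every DMC in exactly one DMR or singleton
        assert dmrs["n_dmcs"].sum() + len(singles) == n
        # oracle per (chrom, direction)
        n_regions = n_singles = 0
        for (c, d), grp in dmcs.groupby(["chrom", "direction"]):
            chains = _chain_oracle(sorted(grp["pos"]), 250)
            n_regions += sum(1 for ch in chains if len(ch) >= 2)
            n_singles += sum(1 for ch in chains if len(ch) == 1)
            for ch in chains:
                if len(ch) >= 2:
                    row = dmrs[(dmrs.chrom == c) & (dmrs.direction == d)
                               & (dmrs.start == ch[0])]
                    assert len(row) == 1 and row.iloc[0].end == ch[-1]
                    assert row.iloc[0].n_dmcs == len(ch)
        assert len(dmrs) == n_regions and len(singles) == n_singles

    def test_idempotent_on_own_members(self):
        dmcs = _dmc_frame("chr1", [10, 100, 200, 600, 700], ["hyper"] * 5)
        dmrs, _ = md.merge_dmrs(dmcs)
        # re-merging each region's members reproduces that single region
        for _, r in dmrs.iterrows():
            members = dmcs[(dmcs.pos >= r.start) & (dmcs.pos <= r.end)]
            again, s2 = md.merge_dmrs(members)
            assert len(again) == 1 and len(s2) == 0
            assert again.iloc[0].n_dmcs == r.n_dmcs

    def test_unsorted_input_rejected(self):
        dmcs = _dmc_frame("chr1", [300, 100], ["hypo", "hypo"])
        with pytest.raises(ValueError, match="sorted"):
            md.merge_dmrs(dmcs)

    def test_summary_shape(self):
        dmcs = _dmc_frame("chr1", [0, 100, 600], ["hypo"] * 3)
        s = dmr_summary(*md.merge_dmrs(dmcs))
        assert s["hypo"]["n_dmrs"] == 1 and s["hypo"]["n_singletons"] == 1
        assert s["hyper"]["n_dmrs"] == 0


class TestAnnotateSites:
    def _sets(self):
        genic = RegionSet("genic", pd.DataFrame(
            [("chr1", 0, 500, "promoter"), ("chr1", 300, 900, "exon")],
            columns=["chrom", "start", "end", "category"]))
        return [genic]

    def test_precedence_resolves_overlap(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [400]})
        out = md.annotate_sites(sites, self._sets(),
                                {"genic": ["promoter", "exon"]},
                                {"genic": "intergenic"})
        assert out["genic"].iloc[0] == "promoter"

    def test_fallback_category(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [5000]})
        out = md.annotate_sites(sites, self._sets(),
                                {"genic": ["promoter", "exon"]},
                                {"genic": "intergenic"})
        assert out["genic"].iloc[0] == "intergenic"

    def test_missing_precedence_entry_errors(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [400]})
        with pytest.raises(ValueError, match="precedence"):
            md.annotate_sites(sites, self._sets(), {"genic": ["promoter"]},
                              {"genic": "intergenic"})

    def test_counts_match_brute_force_and_conserve(self):
        rng = np.random.default_rng(4)
        sites = pd.DataFrame({"chrom": "chr1",
                              "pos": np.sort(rng.choice(10_000, 300, replace=False))})
        ivals = []
        start = 0
        cats = ["island", "shore", "shelf"]
        for k in range(40):
            a = int(rng.integers(0, 9_500))
            ivals.append(("chr1", a, a + int(rng.integers(50, 400)),
                          cats[k % 3]))
        regs = RegionSet("cpg", pd.DataFrame(ivals, columns=["chrom", "start",
                                                             "end", "category"]))
        out = md.annotate_sites(sites, [regs], {"cpg": cats}, {"cpg": "open_sea"})
        counts = out["cpg"].value_counts()
        assert counts.sum() == len(sites)
        prio = {c: i for i, c in enumerate(cats)}
        for _, row in out.iterrows():
            hits = [c for (_, s, e, c) in ivals if s <= row.pos < e]
            expect = min(hits, key=prio.get) if hits else "open_sea"
            assert row["cpg"] == expect


class TestEnrichment:
    def test_yates_worked_example(self):
        r = md.enrichment_test((10, 30), (20, 30))
        assert r["chi2"] == pytest.approx(5.4)
        assert r["p"] == pytest.approx(0.0201, abs=2e-4)
        assert r["direction"] == "depleted"

    def test_equal_proportions_not_enriched(self):
        r = md.enrichment_test((10, 100), (100, 1000))
        assert r["direction"] == "equal"

    def test_tiny_counts_not_significant(self):
        r = md.enrichment_test((2, 4), (3, 10))
        assert r["p"] > 0.05
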