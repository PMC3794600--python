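"""Read binning, region aggregation and density summaries."""

import numpy as np
import pandas as pd
import pytest

from methexpr.core import BIN_INDICES, GeneModel, ReadSet, SubtypeTable, UsageError
from methexpr.profiles import (
    BinnedMethylation,
    bin_reads,
    combine_cell_lines,
    density_summary,
    filter_low_coverage,
    region_level,
)
from methexpr.regions import build_region_catalog


@pytest.fixture(scope="module")
def catalog():
    gene = GeneModel("g1", "chr1", "+", ((50_000, 50_200), (50_700, 50_900)))
    return build_region_catalog([gene])


def counts_of(df, gene, bins):
    return [df.loc[(gene, b)].iloc[0] for b in bins]


class TestBinReads:
    def test_read_spanning_boundary_increments_both_bins(self, catalog):
        rs = ReadSet("CL1", (("chr1", 49_950, 50_050),))
        df = bin_reads(rs, catalog)
        assert counts_of(df, "g1", [-1, 0]) == [1.0, 1.0]
        assert df.to_numpy().sum() == 2.0

    def test_read_outside_all_windows(self, catalog):
        rs = ReadSet("CL1", (("chr1", 500_000, 500_050),))
        assert bin_reads(rs, catalog).to_numpy().sum() == 0.0

    def test_midpoint_rule_single_bin(self, catalog):
        rs = ReadSet("CL1", (("chr1", 49_950, 50_050),))
        df = bin_reads(rs, catalog, rule="midpoint")
        assert df.to_numpy().sum() == 1.0
        assert df.loc[("g1", 0)].iloc[0] == 1.0  # midpoint 50_000 is in bin 0

    def test_per_million_scaling(self, catalog):
        reads = tuple(("chr1", 50_010, 50_020) for _ in range(4))
        rs = ReadSet("CL1", reads)
        df = bin_reads(rs, catalog, normalization="per_million", total_reads=2_000_000)
        assert df.loc[("g1", 0)].iloc[0] == 2.0

    def test_minus_strand_bins_follow_transcription(self):
        gene = GeneModel("gm", "chr1", "-", ((49_800, 50_000),))
        cat = build_region_catalog([gene])
        rs = ReadSet("CL1", (("chr1", 49_990, 49_995),))  # just downstream of TSS
        df = bin_reads(rs, cat)
        assert df.loc[("gm", 0)].iloc[0] == 1.0

    def test_count_conservation_against_per_read_scan(self, catalog):
        rng = np.random.default_rng(3)
        starts = rng.integers(39_000, 61_000, size=200)
        reads = tuple(("chr1", int(s), int(s + rng.integers(20, 300))) for s in starts)
        rs = ReadSet("CL1", reads)
        df = bin_reads(rs, catalog)
        bounds = catalog["g1"].bin_bounds()
        expected = 0
        for _, s, e in reads:
            expected += int(((bounds[:, 0] < e) & (bounds[:, 1] > s)).sum())
        assert df.to_numpy().sum() == expected

    def test_empty_read_set_warns(self, catalog):
        with pytest.warns(UserWarning, match="empty read set"):
            df = bin_reads(ReadSet("CL1", ()), catalog)
        assert df.to_numpy().sum() == 0.0


def make_binned(catalog, bin_values, cell_lines=("A", "B")):
    """BinnedMethylation with given per-bin values replicated per cell line."""
    idx = pd.MultiIndex.from_product([["g1"], list(BIN_INDICES)], names=["gene", "bin"])
    data = pd.DataFrame(0.0, index=idx, columns=list(cell_lines))
    for b, v in bin_values.items():
        data.loc[("g1", b)] = v
    return BinnedMethylation(data)


class TestRegionLevel:
    def test_mean_of_fully_covered_bins(self, catalog):
        binned = make_binned(catalog, {0: 2.0, 1: 4.0})
        lv = region_level(binned, catalog, "Exon1")  # [50_000, 50_200): bins 0-1
        assert lv.loc["g1"].tolist() == [3.0, 3.0]

    def test_all_zero_region(self, catalog):
        binned = make_binned(catalog, {})
        lv = region_level(binned, catalog, "Exon1")
        assert lv.loc["g1"].tolist() == [0.0, 0.0]

    def test_overlap_weighted_mean_on_partial_bin(self, catalog):
        # Intron1 = [50_200, 50_700): bins 2,3,4,5,6 with weights 100 x4 + 100?
        binned = make_binned(catalog, {2: 1.0, 3: 2.0, 4: 3.0, 5: 4.0, 6: 5.0})
        lv = region_level(binned, catalog, "Intron1")
        assert lv.loc["g1", "A"] == pytest.approx(3.0)

    def test_ragged_region_weighting(self):
        # Exon1 [50_000, 50_150): bin 0 fully (100 bp), bin 1 half (50 bp)
        gene = GeneModel("g1", "chr1", "+", ((50_000, 50_150),))
        cat = build_region_catalog([gene])
        binned = make_binned(cat, {0: 2.0, 1: 4.0})
        lv = region_level(binned, cat, "Exon1")
        assert lv.loc["g1", "A"] == pytest.approx((2.0 * 100 + 4.0 * 50) / 150)

    def test_unknown_region_errors(self, catalog):
        binned = make_binned(catalog, {})
        with pytest.raises(UsageError, match="unknown region"):
            region_level(binned, catalog, "Promoter9000")


class TestFilterLowCoverage:
    def _binned(self, totals):
        idx = pd.MultiIndex.from_product(
            [list(totals), [0, 1]], names=["gene", "bin"]
        )
        rows = []
        for g, t in totals.items():
            rows += [[t / 2.0], [t / 2.0]]
        return BinnedMethylation(pd.DataFrame(rows, index=idx, columns=["A"]))

    def test_strict_threshold(self):
        binned = self._binned({"g3": 3, "g4": 4})
        kept = filter_low_coverage(binned, min_reads=3)
        assert kept.gene_ids == ("g4",)

    def test_empty_result_allowed(self):
        binned = self._binned({"g1": 1})
        assert filter_low_coverage(binned).data.empty

    def test_requires_raw_counts(self):
        binned = self._binned({"g4": 4})
        binned.normalization = "per_million"
        with pytest.raises(UsageError):
            filter_low_coverage(binned)


class TestDensitySummary:
    @pytest.fixture
    def subtypes(self):
        entries = [(f"L{i}", "Lu") for i in range(2)]
        entries += [(f"A{i}", "BaA") for i in range(2)]
        entries += [(f"B{i}", "BaB") for i in range(2)]
        return SubtypeTable(tuple(entries))

    def test_truncation_and_zero_exclusion(self, subtypes):
        levels = pd.DataFrame(
            [[120.0, 80.0, 120.0, 80.0, 120.0, 80.0], [0.0] * 6],
            index=["g1", "g2"],
            columns=[cl for cl, _ in subtypes.entries],
        )
        summary = density_summary(levels, subtypes, truncate_at=100.0)
        for st in ("Lu", "BaA", "BaB"):
            p = summary.probabilities[st]
            assert p.sum() == pytest.approx(1.0)
            # two values survive per subtype: 80 and truncated 100
            assert p[p > 0].tolist() == [0.5, 0.5]
            assert summary.fraction_above[st][50.0] == 1.0

    def test_all_zero_errors(self, subtypes):
        levels = pd.DataFrame(
            [[0.0] * 6], index=["g1"], columns=[cl for cl, _ in subtypes.entries]
        )
        with pytest.raises(UsageError):
            density_summary(levels, subtypes)

    def test_planted_hypermethylation_shifts_the_tail(self, small_dataset):
        from methexpr.profiles import region_levels

        ds = small_dataset
        lv = region_level(ds.binned, ds.catalog, "TSS1-1000")
        summary = density_summary(lv, ds.subtypes, truncate_at=100.0, thresholds=(10.0,))
        # effects were planted cycling Lu first, so the Lu tail is heaviest
        assert summary.fraction_above["Lu"][10.0] > summary.fraction_above["BaB"][10.0]
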