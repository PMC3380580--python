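"""Per-CpG aggregation, pooling behaviour and metagene profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from genebody.annotation import GeneLocus, derive_regions
from genebody.intervals import GenomicInterval
from genebody.methylation import (
    CpGIndex,
    genic_vs_intergenic,
    metagene_profile,
    region_methylation,
)

from oracles import naive_region_mean, standard_error


def make_index(sites):
    """sites: list of (chrom, pos, percent)."""
    df = pd.DataFrame(
        {
            "chrom": [s[0] for s in sites],
            "start": [s[1] for s in sites],
            "end": [s[1] + 1 for s in sites],
            "percent": [s[2] for s in sites],
            "coverage": [5] * len(sites),
        }
    )
    return CpGIndex(df)


class TestRegionMethylation:
    def test_unweighted_mean_of_two_sites(self):
        index = make_index([("chr1", 10, 50.0), ("chr1", 20, 100.0)])
        rm = region_methylation(index, {"chr1": [(0, 100)]})
        assert rm.mean_percent == 75.0 and rm.n_sites == 2

    def test_empty_region_is_missing_not_zero(self):
        index = make_index([("chr1", 10, 50.0)])
        rm = region_methylation(index, {"chr1": [(100, 200)]})
        assert rm.missing and math.isnan(rm.mean_percent) and rm.n_sites == 0

    def test_disjoint_regions_pool_by_site_count(self):
        # region A: 3 sites at mean 20, region B: 1 site at 60 -> (3*20+60)/4
        index = make_index(
            [("chr1", 1, 10.0), ("chr1", 2, 20.0), ("chr1", 3, 30.0), ("chr1", 50, 60.0)]
        )
        rm = region_methylation(index, {"chr1": [(0, 10), (40, 60)]})
        assert rm.mean_percent == pytest.approx(30.0)
        assert rm.n_sites == 4

    def test_overlapping_query_regions_count_sites_once(self):
        index = make_index([("chr1", 5, 40.0)])
        rm = region_methylation(index, {"chr1": [(0, 10), (4, 8)]})
        assert rm.n_sites == 1

    def test_accepts_genomic_intervals(self):
        index = make_index([("chr1", 5, 40.0), ("chr2", 5, 80.0)])
        rm = region_methylation(
            index, [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)]
        )
        assert rm.mean_percent == 60.0

    def test_rejects_percent_out_of_range(self):
        with pytest.raises(ValueError, match="percent"):
            make_index([("chr1", 5, 140.0)])

    @given(st.integers(0, 99))
    def test_matches_naive_site_enumeration(self, seed):
        rng = np.random.default_rng(4_000_000 + seed)
        n = int(rng.integers(1, 60))
        sites = [
            ("chrT", int(rng.integers(0, 1000)), float(rng.uniform(0, 100)))
            for _ in range(n)
        ]
        # drop duplicate positions: each covered cytosine is one record
        seen, uniq = set(), []
        for s in sites:
            if s[1] not in seen:
                seen.add(s[1])
                uniq.append(s)
        regions = [
            ("chrT", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 900, 4), rng.integers(10, 300, 4))
        ]
        index = make_index(uniq)
        rm = region_methylation(index, {"chrT": [(s, e) for _, s, e in regions]})
        mean, count = naive_region_mean(uniq, regions)
        assert rm.n_sites == count
        if count:
            assert rm.mean_percent == pytest.approx(mean)

    def test_min_coverage_filter(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chr1\t10\t11\t50\t1\nchr1\t20\t21\t100\t9\n")
        deep = CpGIndex.from_tsv(path, min_coverage=5)
        assert deep.n_sites == 1
        assert CpGIndex.from_tsv(path).n_sites == 2


class TestMetageneProfile:
    def _regions(self, start, end, strand, chrom="chr1"):
        span = GenomicInterval(chrom, start, end, strand)
        locus = GeneLocus("L1", span, (span.pair,), ("tx",))
        return derive_regions(locus)

    def test_plus_strand_offset_zero_is_first_downstream_window(self):
        # one CpG at 60% right at the TSS, another outside the window
        index = make_index([("chr1", 10_050, 60.0), ("chr1", 10_150, 10.0)])
        regs = self._regions(10_000, 20_000, "+")
        df = metagene_profile([regs], index, {"L1": 1})
        row = df[(df.anchor == "TSS") & (df.offset == 0)].iloc[0]
        assert row.mean_percent == 60.0 and row.n_genes == 1

    def test_minus_strand_profile_mirrors_plus_strand(self):
        # mirror of the plus-strand case through genome length L
        L = 30_000
        index_plus = make_index([("chr1", 10_050, 60.0), ("chr1", 12_345, 25.0)])
        index_minus = make_index(
            [("chr1", L - 10_051, 60.0), ("chr1", L - 12_346, 25.0)]
        )
        plus = metagene_profile([self._regions(10_000, 20_000, "+")], index_plus, {"L1": 1})
        minus = metagene_profile(
            [self._regions(L - 20_000, L - 10_000, "-")], index_minus, {"L1": 1}
        )
        merged = plus.merge(minus, on=["bin", "anchor", "offset"], suffixes=("_p", "_m"))
        assert len(merged) == len(plus)
        pd.testing.assert_series_equal(
            merged["mean_percent_p"], merged["mean_percent_m"], check_names=False
        )

    def test_bin_value_is_gene_weighted_mean(self):
        index = make_index([("chr1", 10_050, 40.0), ("chr1", 110_050, 60.0)])
        regs = [
            self._regions(10_000, 20_000, "+"),
            self._regions(110_000, 120_000, "+"),
        ]
        import dataclasses

        regs[1] = dataclasses.replace(regs[1], locus_id="L2")
        df = metagene_profile(regs, index, {"L1": 1, "L2": 1})
        row = df[(df.anchor == "TSS") & (df.offset == 0)].iloc[0]
        assert row.mean_percent == 50.0 and row.n_genes == 2

    def test_missing_windows_stay_missing(self):
        index = make_index([("chr1", 10_050, 40.0)])
        df = metagene_profile([self._regions(10_000, 20_000, "+")], index, {"L1": 1})
        far = df[(df.anchor == "TSS") & (df.offset == 4900)].iloc[0]
        assert math.isnan(far.mean_percent) and far.n_genes == 0

    def test_window_count_matches_flank_extent(self):
        index = make_index([("chr1", 10_050, 40.0)])
        df = metagene_profile([self._regions(10_000, 20_000, "+")], index, {"L1": 1})
        assert len(df[df.anchor == "TSS"]) == (3000 + 5000) // 100
        assert len(df[df.anchor == "TTS"]) == (5000 + 3000) // 100


class TestGenicVsIntergenic:
    def _loci(self, spans):
        return [
            GeneLocus(
                f"L{i}",
                GenomicInterval("chr1", s, e, "+"),
                ((s, e),),
                (f"t{i}",),
            )
            for i, (s, e) in enumerate(spans)
        ]

    def test_genic_exceeds_intergenic_in_trivial_case(self):
        index = make_index(
            [("chr1", 110, 80.0), ("chr1", 120, 80.0), ("chr1", 500, 20.0), ("chr1", 600, 20.0)]
        )
        out = genic_vs_intergenic(index, self._loci([(100, 200)]), {"chr1": 1000})
        assert out["genic"]["mean"] == 80.0
        assert out["intergenic"]["mean"] == 20.0
        assert out["genic"]["n"] + out["intergenic"]["n"] == 4

    def test_all_intergenic_leaves_genic_missing(self):
        index = make_index([("chr1", 500, 20.0)])
        out = genic_vs_intergenic(index, self._loci([(100, 200)]), {"chr1": 1000})
        assert out["genic"]["n"] == 0 and math.isnan(out["genic"]["mean"])

    def test_standard_error_matches_textbook_formula(self):
        index = make_index([("chr1", 110, 10.0), ("chr1", 120, 20.0), ("chr1", 130, 30.0)])
        out = genic_vs_intergenic(index, self._loci([(100, 200)]), {"chr1": 1000})
        assert out["genic"]["se"] == pytest.approx(10.0 / math.sqrt(3))
        assert out["genic"]["se"] == pytest.approx(standard_error([10.0, 20.0, 30.0]))

    @given(st.integers(0, 29))
    def test_site_count_conservation(self, seed):
        rng = np.random.default_rng(5_000_000 + seed)
        sites = [
            ("chr1", int(p), float(rng.uniform(0, 100)))
            for p in rng.choice(1000, size=int(rng.integers(1, 80)), replace=False)
        ]
        spans = sorted(
            (int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 800, 3), rng.integers(20, 200, 3))
        )
        index = make_index(sites)
        out = genic_vs_intergenic(index, self._loci(spans), {"chr1": 1000})
        assert out["genic"]["n"] + out["intergenic"]["n"] == len(sites)
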