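"""Tag densities, CAGE activity, cluster assignment and the intron partition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from genebody.annotation import GeneLocus, derive_regions
from genebody.coverage import (
    TagSet,
    assign_clusters,
    cage_activity,
    intronic_cage_level,
    partition_introns,
    tag_density,
)
from genebody.intervals import GenomicInterval, total_length

from oracles import naive_partition, naive_tag_count


def make_tagset(positions, chrom="chr1", assay="pol2"):
    return TagSet(assay, {chrom: np.asarray(positions, dtype=np.int64)})


def clusters_frame(rows):
    """rows: list of (chrom, start, end, tag_count)."""
    return pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "name": [f"c{i}" for i in range(len(rows))],
            "tag_count": [r[3] for r in rows],
        }
    )


def gene_regions(start, end, strand="+", exons=None, locus_id="L1"):
    span = GenomicInterval("chr1", start, end, strand)
    locus = GeneLocus(locus_id, span, tuple(exons or [span.pair]), ("tx",))
    return derive_regions(locus)


class TestTagDensity:
    def test_ten_tags_per_kilobase(self):
        tags = make_tagset(range(0, 1000, 100))
        assert tag_density(tags, {"chr1": [(0, 1000)]}) == 0.01

    def test_no_tags_zero_density(self):
        tags = make_tagset([5000, 6000])
        assert tag_density(tags, {"chr1": [(0, 1000)]}) == 0.0

    def test_linearity_in_tag_multiplicity(self):
        single = make_tagset([10, 200, 900])
        double = make_tagset([10, 10, 200, 200, 900, 900])
        region = {"chr1": [(0, 1000)]}
        assert tag_density(double, region) == 2 * tag_density(single, region)

    def test_empty_region_set_raises(self):
        with pytest.raises(ValueError, match="empty region"):
            tag_density(make_tagset([1]), {"chr1": []})

    def test_tag_start_rule_membership(self):
        # a tag starting at the region end is outside (half-open)
        tags = make_tagset([999, 1000])
        assert tag_density(tags, {"chr1": [(0, 1000)]}) == pytest.approx(1 / 1000)

    @given(st.integers(0, 99))
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(6_000_000 + seed)
        positions = rng.integers(0, 2000, int(rng.integers(1, 100)))
        regions = [
            (int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 1800, 3), rng.integers(10, 400, 3))
        ]
        tags = make_tagset(positions)
        got = tags.count_in({"chr1": regions})
        expected = naive_tag_count(
            [("chr1", int(p)) for p in positions], [("chr1", s, e) for s, e in regions]
        )
        assert got == expected


class TestCageActivity:
    @pytest.mark.parametrize(
        "start, end, tags, expected",
        [(0, 100, 50, 0.5), (10, 11, 1, 1.0), (0, 3, 7, 7 / 3)],
    )
    def test_tags_per_cluster_bp(self, start, end, tags, expected):
        df = clusters_frame([("chr1", start, end, tags)])
        assert cage_activity(df).iloc[0] == pytest.approx(expected)


class TestAssignClusters:
    def test_midpoint_in_intron_is_intronic_even_when_straddling(self):
        regs = gene_regions(0, 10_000, exons=[(0, 1000), (5000, 10_000)])
        # straddles the exon/intron boundary at 5000, midpoint 4950 in intron
        df = assign_clusters(clusters_frame([("chr1", 4900, 5001, 30)]), [regs])
        assert df.loc[0, "cluster_class"] == "intronic"
        assert df.loc[0, "locus_id"] == "L1"

    def test_contained_rule_rejects_straddling_cluster(self):
        regs = gene_regions(0, 10_000, exons=[(0, 1000), (5000, 10_000)])
        df = assign_clusters(
            clusters_frame([("chr1", 9990, 10_005, 5)]), [regs], rule="contained"
        )
        assert df.loc[0, "cluster_class"] == "intergenic"

    def test_near_tss_cluster_is_canonical(self):
        regs = gene_regions(1000, 9000)
        df = assign_clusters(clusters_frame([("chr1", 1000, 1100, 9)]), [regs])
        assert df.loc[0, "cluster_class"] == "canonical"
        assert df.loc[0, "tss_offset"] == 0

    def test_outside_any_locus_is_intergenic(self):
        regs = gene_regions(1000, 9000)
        df = assign_clusters(clusters_frame([("chr1", 20_000, 20_100, 9)]), [regs])
        assert df.loc[0, "cluster_class"] == "intergenic"
        assert df.loc[0, "locus_id"] is None

    def test_minus_strand_tss_offset_is_oriented(self):
        regs = gene_regions(1000, 9000, strand="-")
        # cluster hugging the 3' genomic end = the TSS of a minus-strand gene
        df = assign_clusters(clusters_frame([("chr1", 8900, 9000, 9)]), [regs])
        assert df.loc[0, "cluster_class"] == "canonical"
        assert df.loc[0, "tss_offset"] == 0


class TestIntronicCageLevel:
    def test_tags_over_intron_bp(self):
        regs = gene_regions(0, 12_000, exons=[(0, 1000), (11_000, 12_000)])
        clusters = assign_clusters(clusters_frame([("chr1", 5000, 5100, 30)]), [regs])
        assert intronic_cage_level(regs, clusters) == pytest.approx(30 / 10_000)

    def test_no_intronic_clusters_gives_zero(self):
        regs = gene_regions(0, 12_000, exons=[(0, 1000), (11_000, 12_000)])
        # the only cluster is canonical, so the intronic level is 0
        clusters = assign_clusters(clusters_frame([("chr1", 500, 600, 5)]), [regs])
        assert intronic_cage_level(regs, clusters) == 0.0

    def test_locus_without_introns_is_missing(self):
        regs = gene_regions(0, 12_000)
        clusters = assign_clusters(clusters_frame([("chr1", 5000, 5100, 30)]), [regs])
        assert math.isnan(intronic_cage_level(regs, clusters))

    def test_locus_denominator_option(self):
        regs = gene_regions(0, 12_000, exons=[(0, 1000), (11_000, 12_000)])
        clusters = assign_clusters(clusters_frame([("chr1", 5000, 5100, 30)]), [regs])
        assert intronic_cage_level(regs, clusters, denominator="locus") == pytest.approx(
            30 / 12_000
        )

    def test_closed_form_when_clusters_nest_in_introns(self):
        regs = gene_regions(0, 20_000, exons=[(0, 1000), (19_000, 20_000)])
        rows = [("chr1", 2000, 2100, 10), ("chr1", 8000, 8200, 25)]
        clusters = assign_clusters(clusters_frame(rows), [regs])
        assert intronic_cage_level(regs, clusters) == pytest.approx(
            (10 + 25) / total_length(regs.introns)
        )


class TestPartitionIntrons:
    def test_single_cluster_fraction(self):
        part = partition_introns([(0, 1000)], [(100, 200)])
        assert total_length(part.initiation) == 100
        assert part.fraction_initiation == pytest.approx(0.1)

    def test_no_clusters_all_silent(self):
        part = partition_introns([(0, 1000)], [])
        assert part.initiation == ()
        assert total_length(part.silent) == 1000
        assert part.fraction_initiation == 0.0

    def test_overlapping_clusters_union_not_sum(self):
        part = partition_introns([(0, 1000)], [(100, 200), (150, 250)])
        assert total_length(part.initiation) == 150

    def test_empty_introns_raise(self):
        with pytest.raises(ValueError, match="non-empty"):
            partition_introns([], [(0, 10)])

    @given(st.integers(0, 99))
    def test_matches_per_bp_scan_and_conserves_bp(self, seed):
        rng = np.random.default_rng(7_000_000 + seed)
        introns = [
            (int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 900, 3), rng.integers(10, 100, 3))
        ]
        introns = sorted(set(introns))
        clusters = [
            (int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 950, 4), rng.integers(5, 80, 4))
        ]
        part = partition_introns(introns, clusters)
        init_bp, silent_bp, init_set = naive_partition(introns, clusters, 1100)
        assert total_length(part.initiation) == init_bp
        assert total_length(part.silent) == silent_bp
        assert total_length(part.initiation) + total_length(part.silent) == total_length(
            introns
        )
        got_init = {x for s, e in part.initiation for x in range(s, e)}
        assert got_init == init_set
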