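import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polreloc as pr
from polreloc.annotation import (
    DEFAULT_TILING,
    FlaggedInterval,
    TilingConvention,
    tss_relative_window,
)
from polreloc.io import load_annotation


GFF = """##gff-version 3
##sequence-region chr1 1 50000
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=GPLUS
chr1\tsrc\tgene\t101\t400\t.\t-\t.\tID=GMINUS
"""


class TestLoadAnnotation:
    def test_plus_strand_coordinate_conversion(self):
        ann = load_annotation(io.StringIO(GFF))
        g = ann.gene("GPLUS")
        assert (g.interval.start, g.interval.end) == (100, 400)
        assert g.tss == 100

    def test_minus_strand_tss_is_interval_end(self):
        ann = load_annotation(io.StringIO(GFF))
        assert ann.gene("GMINUS").tss == 400

    def test_missing_rp_id_warns_but_loads(self):
        with pytest.warns(UserWarning, match="RPL16B"):
            ann = load_annotation(io.StringIO(GFF), rp_gene_ids={"RPL16B"})
        assert len(ann.genes) == 2
        assert not any(g.is_rp for g in ann.genes)

    def test_duplicate_gene_id_is_an_error(self):
        bad = GFF + "chr1\tsrc\tgene\t501\t600\t.\t+\t.\tID=GPLUS\n"
        with pytest.raises(Exception, match="duplicate"):
            load_annotation(io.StringIO(bad))


class TestTileGenome:
    def test_both_ends_trim_arithmetic(self):
        bins = pr.tile_genome(
            {"c": 1000}, bin_size=200, end_trim=200,
            convention=TilingConvention(trim_both=True),
        )
        assert len(bins) == 3
        assert bins[0].interval.start == 200
        assert bins[-1].interval.end == 800

    def test_short_chromosome_yields_no_bins(self):
        bins = pr.tile_genome(
            {"c": 350}, convention=TilingConvention(trim_both=True)
        )
        assert bins == []

    def test_r64_assembly_bin_total(self):
        bins = pr.tile_genome(pr.R64_CHROM_LENGTHS)
        assert len(bins) == 60333

    def test_calibration_search_finds_unique_convention(self):
        hits = pr.calibrate_tiling_convention(pr.R64_CHROM_LENGTHS, 60333)
        assert hits == [TilingConvention(trim_both=False, include_mito=False)]

    def test_bins_disjoint_sorted_and_indexed(self):
        bins = pr.tile_genome({"a": 2000, "b": 1100})
        assert [b.index for b in bins] == list(range(len(bins)))
        for prev, cur in zip(bins, bins[1:]):
            if prev.interval.chrom == cur.interval.chrom:
                assert prev.interval.end <= cur.interval.start
        per_chrom = sum(
            len(pr.tile_genome({c: l})) for c, l in {"a": 2000, "b": 1100}.items()
        )
        assert len(bins) == per_chrom

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        lengths=st.lists(st.integers(100, 5000), min_size=1, max_size=5),
        bin_size=st.integers(50, 400),
        end_trim=st.integers(0, 500),
    )
    def test_tiling_invariants_hold_for_arbitrary_genomes(
        self, lengths, bin_size, end_trim
    ):
        chroms = {f"c{i}": l for i, l in enumerate(lengths)}
        bins = pr.tile_genome(chroms, bin_size, end_trim)
        assert all(b.interval.length == bin_size for b in bins)
        assert [b.index for b in bins] == list(range(len(bins)))
        for a, b in zip(bins, bins[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end <= b.interval.start
        for b in bins:
            assert b.interval.end <= chroms[b.interval.chrom] - end_trim

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            pr.tile_genome({"a": 1000}, bin_size=0)
        with pytest.raises(ValueError):
            pr.tile_genome({"a": 1000}, end_trim=-1)


def _gene(chrom, start, end, strand, ann_len=50_000):
    ann = pr.GenomeAnnotation(
        {chrom: ann_len},
        [pr.GeneModel("G", pr.Interval(chrom, start, end), strand)],
    )
    return ann.gene("G"), ann


class TestUpstreamSubregions:
    def test_plus_strand_layout(self):
        g, ann = _gene("c", 10_000, 12_000, "+")
        subs = pr.upstream_subregions(g, ann)
        assert [(s.start, s.end) for s in subs] == [
            (9000, 9200), (9200, 9400), (9400, 9600), (9600, 9800), (9800, 10000),
        ]
        assert not any(s.truncated for s in subs)

    def test_minus_strand_reflection(self):
        g, ann = _gene("c", 8_000, 10_000, "-")
        subs = pr.upstream_subregions(g, ann)
        assert [(s.start, s.end) for s in subs] == [
            (10800, 11000), (10600, 10800), (10400, 10600), (10200, 10400),
            (10000, 10200),
        ]

    def test_truncation_near_chromosome_start(self):
        g, ann = _gene("c", 300, 2_000, "+")
        subs = pr.upstream_subregions(g, ann)
        assert subs[0].empty and subs[0].truncated
        assert subs[1].empty and subs[1].truncated
        assert subs[2].empty and subs[2].truncated
        assert (subs[3].start, subs[3].end) == (0, 100) and subs[3].truncated
        assert (subs[4].start, subs[4].end) == (100, 300)

    def test_subregions_partition_the_upstream_kilobase(self):
        for start, strand in [(5_000, "+"), (5_000, "-"), (30_000, "+")]:
            g, ann = _gene("c", start, start + 1_000, strand)
            subs = pr.upstream_subregions(g, ann)
            ivs = sorted((s.start, s.end) for s in subs if not s.empty)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2  # contiguous, disjoint
            assert sum(e - s for s, e in ivs) == 1_000


class TestUrsWindow:
    def test_plus_strand(self):
        g, ann = _gene("c", 10_000, 12_000, "+")
        w = pr.urs_window(g, ann)
        assert (w.start, w.end) == (9_400, 9_900)

    def test_minus_strand(self):
        g, ann = _gene("c", 8_000, 10_000, "-")
        w = pr.urs_window(g, ann)
        assert (w.start, w.end) == (10_100, 10_600)

    def test_off_chromosome_window_is_empty_flagged(self):
        g, ann = _gene("c", 50, 1_500, "+")
        w = pr.urs_window(g, ann)
        assert w.empty and w.truncated

    def test_window_is_500bp_and_inside_subregions(self):
        g, ann = _gene("c", 10_000, 12_000, "+")
        w = pr.urs_window(g, ann)
        assert w.length == 500
        subs = pr.upstream_subregions(g, ann)
        union_lo = min(s.start for s in subs)
        union_hi = max(s.end for s in subs)
        assert union_lo <= w.start and w.end <= union_hi


def test_tss_relative_window_strandedness():
    g, ann = _gene("c", 10_000, 12_000, "-")
    w = tss_relative_window(g, ann, -200, -100)
    # minus strand: -200..-100 lies genomically right of the TSS (=12000)
    assert (w.start, w.end) == (12_100, 12_200)
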