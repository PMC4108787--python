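import numpy as np
import pytest

from mitoblocks.aligner import AlignParams, LocalAlignment, local_align
from mitoblocks.genome_io import CircularInterval, GenomeRecord, union_length
from mitoblocks.synteny import (
    ContainmentError,
    Placement,
    SyntenicBlock,
    aligned_fraction,
    build_blocks,
    edge_proximity,
    junctions_to_table,
    order_and_junctions,
    unique_regions,
)

from .conftest import random_seq


def aln(qs, qe, ss, se, gq="A", gs="B", ident=99.0, orient="forward"):
    span = qe - qs
    return LocalAlignment(
        q=CircularInterval(gq, qs, qe),
        s=CircularInterval(gs, ss, se),
        orientation=orient,
        identity=ident,
        aln_len=span,
        n_mismatch=0,
        n_gapcols=0,
        score=span,
    )


class TestBuildBlocks:
    def test_empty_input_gives_empty_list(self):
        assert build_blocks([]) == []

    def test_identical_circles_give_one_block(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 50_000)
        A, B = GenomeRecord("A", s), GenomeRecord("B", s)
        hits = local_align(A, B, AlignParams(min_len=500, min_ident=90.0))
        blocks = build_blocks(hits, 2000, 95.0)
        assert len(blocks) == 1
        assert {p.genome_id for p in blocks[0].placements} == {"A", "B"}
        assert all(p.interval.span == 50_000 for p in blocks[0].placements)

    def test_threshold_filtering(self):
        hits = [aln(0, 5000, 0, 5000), aln(6000, 7000, 6000, 7000)]  # 1 kb too short
        blocks = build_blocks(hits, 2000, 95.0)
        assert len(blocks) == 1

    def test_labels_assigned_in_descending_span_order(self):
        hits = [aln(0, 3000, 0, 3000), aln(10_000, 20_000, 10_000, 20_000)]
        blocks = build_blocks(hits, 2000, 95.0)
        assert [b.label for b in blocks] == ["1", "2"]
        assert blocks[0].length == 10_000

    def test_duplicated_placement_gets_prime_suffix(self):
        # one subject interval matched by two disjoint query intervals
        hits = [aln(0, 5000, 0, 5000), aln(20_000, 25_000, 30, 5030)]
        blocks = build_blocks(hits, 2000, 95.0)
        assert len(blocks) == 1
        labels = sorted(p.label for p in blocks[0].placements if p.genome_id == "A")
        assert labels == ["1", "1′"]

    def test_planted_blocks_in_permuted_order(self, small_pair, small_result):
        A, B, truth = small_pair
        blocks = small_result["blocks"]
        assert len(blocks) == len({p.label for p in truth.placements[A.id]})
        # placements recovered in planted order on each genome
        for gid in (A.id, B.id):
            got = sorted(
                (p.interval.start for b in blocks for p in b.on(gid))
            )
            planted = sorted(p.interval.start for p in truth.placements[gid])
            assert all(abs(g - t) <= 20 for g, t in zip(got, planted))


def placements_block(label, *ivs):
    return SyntenicBlock(
        label=label,
        placements=[Placement("G", iv, "forward", label) for iv in ivs],
        length=ivs[0].span,
    )


class TestJunctions:
    def test_single_full_circle_block_yields_no_junctions(self):
        g = GenomeRecord("G", "A" * 1000)
        b = placements_block("1", CircularInterval("G", 0, 1000))
        assert order_and_junctions(g, b and [b]) == []

    def test_overlap_abutting_and_gap(self):
        g = GenomeRecord("G", "A" * 10_000)
        blocks = [
            placements_block("1", CircularInterval("G", 0, 3_000)),
            placements_block("2", CircularInterval("G", 2_700, 6_000)),  # 300 bp overlap
            placements_block("3", CircularInterval("G", 6_000, 8_000)),  # abutting
        ]
        js = order_and_junctions(g, blocks)
        assert len(js) == 3
        by_pair = {(j.left_block, j.right_block): j for j in js}
        assert by_pair[("1", "2")].type == "overlap"
        assert by_pair[("1", "2")].overlap_len == 300
        assert by_pair[("2", "3")].type == "abutting"
        wrap = by_pair[("3", "1")]
        assert wrap.type == "gap" and wrap.gap_interval.span == 2_000

    def test_junction_count_equals_placement_count(self, small_pair, small_result):
        A, B, _ = small_pair
        for g in (A, B):
            n_placements = sum(
                len(b.on(g.id)) for b in small_result["blocks"]
            )
            assert len(small_result["junctions"][g.id]) == n_placements

    def test_containment_raises(self):
        g = GenomeRecord("G", "A" * 10_000)
        blocks = [
            placements_block("1", CircularInterval("G", 0, 5_000)),
            placements_block("2", CircularInterval("G", 1_000, 2_000)),
        ]
        with pytest.raises(ContainmentError):
            order_and_junctions(g, blocks)

    def test_overlap_junctions_match_counterpart_edge_repeats(self, small_pair, small_result):
        """Every overlap junction's shared sequence corresponds to a
        repeated sequence at block edges in the counterpart genome."""
        A, B, truth = small_pair
        for gid, other in ((A.id, B.id), (B.id, A.id)):
            for j in small_result["junctions"][gid]:
                if j.type != "overlap":
                    continue
                # a planted repeat copy of the same length exists in the
                # counterpart genome (the edge-repeat construction)
                assert any(
                    abs(r.span - j.overlap_len) <= 20
                    for r in truth.repeats[other]
                ), f"overlap junction {j} has no counterpart edge repeat"

    def test_junction_table_columns(self, small_result):
        t = junctions_to_table(
            [j for js in small_result["junctions"].values() for j in js]
        )
        assert list(t.columns) == ["genome", "left", "right", "type", "bp"]


class TestUniqueRegions:
    def test_identical_genomes_have_zero_unique(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 30_000)
        A, B = GenomeRecord("A", s), GenomeRecord("B", s)
        hits = local_align(A, B, AlignParams(min_len=500, min_ident=90.0))
        blocks = build_blocks(hits, 2000, 95.0)
        assert unique_regions(A, blocks).total_unique_bp == 0

    def test_planted_inserts_and_top2_share(self):
        g = GenomeRecord("G", "A" * 100_000)
        blocks = [
            placements_block("1", CircularInterval("G", 0, 40_000)),
            placements_block("2", CircularInterval("G", 50_000, 88_000)),
        ]
        rep = unique_regions(g, blocks)
        assert rep.total_unique_bp == 22_000
        assert len(rep.regions) == 2
        assert rep.largest_regions_share == 100.0

    def test_truth_unique_bp_recovered(self, small_pair, small_result):
        A, B, truth = small_pair
        for g in (A, B):
            assert (
                abs(small_result["unique"][g.id].total_unique_bp - truth.unique_bp(g.id))
                <= 30
            )

    def test_conservation_union_plus_unique_is_L(self, small_pair, small_result):
        A, B, _ = small_pair
        for g in (A, B):
            ivs = [p.interval for b in small_result["blocks"] for p in b.on(g.id)]
            assert union_length(ivs, g.length) + small_result["unique"][
                g.id
            ].total_unique_bp == g.length


class TestAlignedFraction:
    def test_genome_vs_itself_is_100(self):
        rng = np.random.default_rng(2)
        g = GenomeRecord("G", random_seq(rng, 20_000))
        hits = local_align(g, g, AlignParams(min_len=100, min_ident=95.0))
        assert aligned_fraction(g, hits, "query") == 100.0

    def test_planted_80_percent_shared(self):
        rng = np.random.default_rng(3)
        shared = random_seq(rng, 80_000)
        A = GenomeRecord("A", shared + random_seq(rng, 20_000))
        B = GenomeRecord("B", random_seq(rng, 10_000) + shared)
        hits = local_align(A, B, AlignParams(k=11, min_len=50, min_ident=80.0))
        assert aligned_fraction(A, hits, "query") == pytest.approx(80.0, abs=0.2)


class TestEdgeProximity:
    def test_far_apart_sets_are_empty(self):
        g = GenomeRecord("G", "A" * 100_000)
        set1 = [placements_block("1", CircularInterval("G", 0, 10_000))]
        set2 = [placements_block("9", CircularInterval("G", 40_000, 60_000))]
        assert edge_proximity(set1, set2, g, max_dist=2000) == []

    def test_coincident_edges_reported_with_distance(self):
        g = GenomeRecord("G", "A" * 100_000)
        set1 = [placements_block("1", CircularInterval("G", 0, 10_000))]
        set2 = [placements_block("9", CircularInterval("G", 10_499, 30_000))]
        out = edge_proximity(set1, set2, g, max_dist=2000)
        # the end edge of block 1 (position 9,999) is 500 bp from 10,499
        assert any(d == 500 for (_, _, d) in out)
        # each set-1 edge reported at most once
        assert len(out) == len({e1 for (e1, _, _) in out})
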