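import numpy as np
import pytest

from mitoblocks.genome_io import (
    CircularInterval,
    FeatureRecord,
    GenomeRecord,
    revcomp_genome,
    revcomp_interval,
)
from mitoblocks.orfscan import (
    OrfRecord,
    classify_orf,
    compare_genes,
    find_orfs,
    predict_tm,
    screen_candidates,
)
from mitoblocks.repeats import RepeatMatch
from mitoblocks.synteny import Placement, SyntenicBlock

from .conftest import random_seq

NON_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def codons(rng, n):
    return "".join(NON_STOP[i] for i in rng.integers(0, 61, n))


def orf_nt(rng, n_codons):
    return "ATG" + codons(rng, n_codons) + "TAA"


class TestFindOrfs:
    def test_strict_100aa_boundary(self):
        rng = np.random.default_rng(0)
        long_orf = orf_nt(rng, 100)  # 101 aa > 100: reported
        short_orf = orf_nt(rng, 99)  # 100 aa: not reported
        g = GenomeRecord(
            "g",
            random_seq(rng, 1_000) + "TAA" + long_orf + "TAA"
            + random_seq(rng, 500) + "TAA" + short_orf + random_seq(rng, 1_000),
        )
        orfs = find_orfs(g, min_aa=100)
        starts = {(o.interval.start, o.strand) for o in orfs}
        assert (1_003, "+") in starts
        short_start = 1_003 + len(long_orf) + 3 + 500 + 3
        assert (short_start, "+") not in starts
        (planted,) = [o for o in orfs if o.interval.start == 1_003]
        assert planted.aa_len == 101
        assert planted.protein.startswith("M")
        assert planted.aa_len == planted.interval.span // 3 - 1

    def test_origin_spanning_orf_reported_once_with_wraps(self):
        rng = np.random.default_rng(1)
        nt = orf_nt(rng, 150)
        g = GenomeRecord("g", nt[200:] + random_seq(rng, 3_000) + "TAA" + nt[:200])
        L = g.length
        orfs = find_orfs(g, min_aa=100)
        wrapped = [o for o in orfs if o.interval.wraps and o.strand == "+"]
        assert len(wrapped) == 1
        (o,) = wrapped
        assert o.interval.start == L - 200
        assert o.interval.span == len(nt)
        assert o.aa_len == 151

    def test_one_orf_per_frame_and_stop(self):
        # an internal in-frame ATG must not yield a second, nested ORF
        rng = np.random.default_rng(2)
        inner = "ATG" + codons(rng, 110)
        nt = "ATG" + codons(rng, 40) + inner + "TAA"
        g = GenomeRecord("g", random_seq(rng, 600) + "TAA" + nt + random_seq(rng, 600))
        orfs = find_orfs(g, min_aa=100)
        same_stop = [o for o in orfs if o.interval.end == 603 + len(nt) and o.strand == "+"]
        assert len(same_stop) == 1
        assert same_stop[0].interval.start == 603  # the longest ATG reading

    def test_revcomp_returns_mirrored_orfs(self):
        rng = np.random.default_rng(3)
        g = GenomeRecord("g", random_seq(rng, 20_000))
        fwd = find_orfs(g, min_aa=60)
        rev = find_orfs(revcomp_genome(g), min_aa=60)
        L = g.length
        mirrored = {
            (revcomp_interval(o.interval, L).start, "+" if o.strand == "-" else "-")
            for o in fwd
        }
        got = {(o.interval.start, o.strand) for o in rev}
        assert got == mirrored

    def test_known_gene_overlap_flagged(self):
        rng = np.random.default_rng(4)
        nt = orf_nt(rng, 120)
        g = GenomeRecord("g", random_seq(rng, 1_000) + "TAA" + nt + random_seq(rng, 1_000))
        feats = [
            FeatureRecord(CircularInterval("g", 900, 1_400), "cox2", "protein")
        ]
        orfs = find_orfs(g, min_aa=100, features=feats)
        (o,) = [x for x in orfs if x.interval.start == 1_003]
        assert o.overlaps_known_gene

    def test_names_follow_length_convention(self):
        rng = np.random.default_rng(5)
        nt = orf_nt(rng, 130)
        g = GenomeRecord("g", random_seq(rng, 500) + "TAA" + nt + random_seq(rng, 500))
        (o,) = [x for x in find_orfs(g, min_aa=100) if x.interval.start == 503]
        assert o.name.startswith("orf131")


class TestClassifyOrf:
    def make_orf(self, genome, start, end, strand="+"):
        iv = CircularInterval(genome.id, start, end, strand, wraps=end > genome.length)
        nt = genome.fetch_interval(iv)
        from Bio.Seq import Seq

        return OrfRecord(
            name="x", interval=iv, strand=strand,
            protein=str(Seq(nt).translate()).rstrip("*"),
            aa_len=(end - start) // 3 - 1,
        )

    def test_shared_orf_is_identical(self):
        rng = np.random.default_rng(10)
        nt = orf_nt(rng, 120)
        shared = random_seq(rng, 2_000) + nt + random_seq(rng, 2_000)
        A = GenomeRecord("A", random_seq(rng, 1_000) + shared + random_seq(rng, 1_000))
        B = GenomeRecord("B", random_seq(rng, 3_000) + shared + random_seq(rng, 500))
        orf = self.make_orf(A, 3_000, 3_000 + len(nt))
        assert classify_orf(orf, A, B) == "identical"

    def test_snp_orf_is_polymorphic(self):
        rng = np.random.default_rng(11)
        nt = orf_nt(rng, 120)
        mutated = list(nt)
        for p in (60, 180, 300):
            mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
        A = GenomeRecord("A", random_seq(rng, 1_000) + nt + random_seq(rng, 1_000))
        B = GenomeRecord("B", random_seq(rng, 2_000) + "".join(mutated) + random_seq(rng, 800))
        orf = self.make_orf(A, 1_000, 1_000 + len(nt))
        assert classify_orf(orf, A, B) == "polymorphic"

    def test_fusion_orf_is_chimeric(self):
        rng = np.random.default_rng(12)
        counterpart_locus = codons(rng, 80)  # 240 bp, stop-free
        A_nt = "ATG" + counterpart_locus + codons(rng, 80) + "TAA"
        A = GenomeRecord("A", random_seq(rng, 1_500) + A_nt + random_seq(rng, 1_500))
        B = GenomeRecord("B", random_seq(rng, 2_000) + counterpart_locus + random_seq(rng, 2_000))
        orf = self.make_orf(A, 1_500, 1_500 + len(A_nt))
        assert classify_orf(orf, A, B) == "chimeric"

    def test_novel_orf_is_unique(self):
        rng = np.random.default_rng(13)
        nt = orf_nt(rng, 120)
        A = GenomeRecord("A", random_seq(rng, 1_000) + nt + random_seq(rng, 1_000))
        B = GenomeRecord("B", random_seq(rng, 5_000))
        orf = self.make_orf(A, 1_000, 1_000 + len(nt))
        assert classify_orf(orf, A, B) == "unique"


class TestPredictTm:
    def test_poly_aspartate_is_not_tm(self):
        assert predict_tm("D" * 30) == (False, [])

    def test_leucine_stretch_is_tm(self):
        tm, segments = predict_tm("D" * 20 + "L" * 25 + "D" * 20)
        assert tm
        assert len(segments) == 1
        s, e = segments[0]
        # window centers of the hydrophobic run
        assert 20 <= s <= 30 and 35 <= e <= 45

    def test_protein_shorter_than_window(self):
        assert predict_tm("LLLL") == (False, [])

    def test_threshold_is_inclusive_mean(self):
        # alternating L (3.8) and G (-0.4): mean 1.7 >= 1.6 -> TM
        protein = "LG" * 20
        tm, _ = predict_tm(protein, window=19, threshold=1.6)
        assert tm


class TestScreenCandidates:
    def test_empty_orf_list(self):
        g = GenomeRecord("g", "A" * 1000)
        rep = screen_candidates([], [], [], g)
        assert rep.rows == [] and rep.final_candidates == []

    def test_injected_known_gene_is_screened(self):
        """A known gene (a truncated atp6 copy, say) can be pushed through
        the same screen even though it is not a novel ORF."""
        rng = np.random.default_rng(20)
        g = GenomeRecord("g", random_seq(rng, 50_000))
        blocks = [
            SyntenicBlock(
                "1",
                [Placement("g", CircularInterval("g", 0, 9_000), "forward", "1")],
                9_000,
            )
        ]
        reps = [
            RepeatMatch(
                CircularInterval("g", 9_500, 9_800),
                CircularInterval("g", 30_000, 30_300),
                100.0, 300, "direct",
            )
        ]
        pseudo = OrfRecord(
            name="psi-atp6-2",
            interval=CircularInterval("g", 10_000, 10_600),
            strand="+",
            protein="M" + "L" * 30 + "D" * 100,
            aa_len=131,
            orf_class="known",
        )
        rep = screen_candidates([], blocks, reps, g, max_dist=2_000, extra=[pseudo])
        assert rep.final_candidates == ["psi-atp6-2"]
        (row,) = rep.rows
        assert row.orf.dist_block_edge == 10_000 - 9_000 + 1
        assert row.orf.dist_repeat == 10_000 - 9_800 + 1

    def test_candidate_flags_are_conjunctive(self, small_pair, small_result):
        A, _, truth = small_pair
        report = small_result["candidates"][A.id]
        for row in report.rows:
            in_final = row.orf.name in report.final_candidates
            assert in_final == (
                row.is_chimeric_or_unique
                and row.near_block_edge
                and row.near_repeat
                and row.has_tm
            )


def feat(name, L):
    return FeatureRecord(CircularInterval("g", 0, L), name, "protein")


def gene(rng, n_codons):
    return codons(rng, n_codons)


class TestCompareGenes:
    def test_identical_pair_is_silent(self):
        rng = np.random.default_rng(30)
        g = gene(rng, 200)
        polys, skipped = compare_genes([(feat("x", len(g)), g)], [(feat("x", len(g)), g)])
        assert polys == [] and skipped == []

    def test_unmatched_names_are_skipped(self):
        rng = np.random.default_rng(31)
        g = gene(rng, 100)
        polys, skipped = compare_genes(
            [(feat("a", len(g)), g)], [(feat("b", len(g)), g)]
        )
        assert skipped == ["a", "b"]

    def test_synonymous_snp_with_outgroup_polarity(self):
        """A gcA->gcG third-position change is synonymous (Ala); the
        outgroup carrying gcG polarizes the site to the second genome."""
        rng = np.random.default_rng(32)
        base = gene(rng, 659)
        j = base[:903] + "GCA" + base[906:]
        f = base[:903] + "GCG" + base[906:]
        polys, _ = compare_genes(
            [(feat("matR", len(j)), j)],
            [(feat("matR", len(f)), f)],
            [(feat("matR", len(f)), f)],
        )
        (p,) = polys
        assert p.site == 904
        assert p.kind == "SNP_synonymous"
        assert (p.ref_codon, p.alt_codon) == ("GCA", "GCG")
        assert p.aa_change == "A→A"
        assert p.outgroup_state == "matches_second"

    def test_inframe_insertion_reported_at_codon_start(self):
        """A 9 bp in-frame insertion inside codon 6 is reported at site 16
        with the inserted codons translated (TNMQ vs T)."""
        rng = np.random.default_rng(33)
        a4 = gene(rng, 199)
        short = a4[:15] + "ACG" + a4[18:]
        long = short[:17] + "GAATATGCA" + short[17:]
        polys, _ = compare_genes(
            [(feat("atp4", len(long)), long)], [(feat("atp4", len(short)), short)]
        )
        (p,) = polys
        assert p.site == 16
        assert p.kind == "inframe_indel"
        assert p.ref_codon == "ACGAATATGCAG" and p.alt_codon == "ACG"
        assert p.aa_change == "TNMQ→T"

    def test_inframe_deletion_site_and_context(self):
        rng = np.random.default_rng(34)
        r2 = gene(rng, 333)
        long = r2[:336] + "CCCGGGAAGGGGGAT" + r2[351:]
        short = r2[:336] + "CCGGAT" + r2[351:]
        polys, _ = compare_genes(
            [(feat("rpl2", len(long)), long)], [(feat("rpl2", len(short)), short)]
        )
        (p,) = polys
        assert p.site == 337
        assert p.kind == "inframe_indel"
        assert p.aa_change.startswith("PGKG")

    def test_nonsynonymous_mnp_with_editing_caveat(self):
        """tTC->tCT flips Phe to Ser; C-to-U editing at the polymorphic
        positions would restore Phe in both alleles, so the call carries
        the editing-sensitive flag."""
        rng = np.random.default_rng(35)
        s3 = gene(rng, 111)
        jj = s3[:177] + "TTCTTC" + s3[183:]
        ff = s3[:177] + "TCTTTC" + s3[183:]
        polys, _ = compare_genes(
            [(feat("sdh3", len(jj)), jj)],
            [(feat("sdh3", len(ff)), ff)],
            [(feat("sdh3", len(ff)), ff)],
        )
        (p,) = polys
        assert p.site == 178
        assert p.kind == "SNP_nonsynonymous"
        assert p.aa_change == "F→S"
        assert p.editing_sensitive
        assert p.outgroup_state == "matches_second"

    def test_rearranged_three_prime(self):
        rng = np.random.default_rng(36)
        g1 = gene(rng, 432)
        g2 = g1[:816] + gene(rng, 160)
        polys, _ = compare_genes(
            [(feat("atp6", len(g1)), g1)], [(feat("atp6", len(g2)), g2)]
        )
        kinds = {p.kind for p in polys}
        assert kinds == {"rearranged_3prime"}
        (p,) = polys
        assert abs(p.site - 816) <= 25

    def test_rearranged_five_prime(self):
        rng = np.random.default_rng(37)
        g1 = gene(rng, 432)
        g3 = gene(rng, 120) + g1[360:]
        polys, _ = compare_genes(
            [(feat("atp6", len(g1)), g1)], [(feat("atp6", len(g3)), g3)]
        )
        kinds = {p.kind for p in polys}
        assert kinds == {"rearranged_5prime"}
        (p,) = polys
        assert abs(p.site - 361) <= 25
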