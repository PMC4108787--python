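import numpy as np
import pytest

from mitoblocks.aligner import (
    AlignerConfigError,
    AlignParams,
    alignments_to_table,
    dp_oracle_align,
    local_align,
    self_align,
)
from mitoblocks.genome_io import GenomeRecord, reverse_complement, rotate_origin

from .conftest import random_seq


def mutate(rng, seq, n_snps):
    out = list(seq)
    for p in rng.choice(len(seq), size=n_snps, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


class TestLocalAlign:
    def test_repeat_free_linear_self_is_one_full_length_hit(self):
        rng = np.random.default_rng(0)
        g = GenomeRecord("g", random_seq(rng, 10_000), circular=False)
        hits = local_align(g, g, AlignParams(min_len=100, min_ident=95.0))
        assert len(hits) == 1
        (h,) = hits
        assert (h.q.start, h.q.end) == (0, 10_000)
        assert h.identity == 100.0 and h.orientation == "forward"

    def test_identical_circles_are_one_full_circle_block(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 8_000)
        hits = local_align(
            GenomeRecord("a", s), GenomeRecord("b", s), AlignParams(min_len=100, min_ident=95.0)
        )
        assert len(hits) == 1
        assert hits[0].q.span == 8_000 and hits[0].s.span == 8_000

    def test_planted_segment_recovered_within_20bp(self):
        rng = np.random.default_rng(2)
        seg = random_seq(rng, 2_500)
        seg_mut = mutate(rng, seg, 100)  # 96% identity
        A = GenomeRecord("A", random_seq(rng, 10_000) + seg + random_seq(rng, 17_500))
        B = GenomeRecord("B", random_seq(rng, 5_000) + seg_mut + random_seq(rng, 22_500))
        hits = local_align(A, B, AlignParams(min_len=2000, min_ident=90.0))
        assert len(hits) == 1
        (h,) = hits
        assert abs(h.q.start - 10_000) <= 20 and abs(h.q.end - 12_500) <= 20
        assert abs(h.s.start - 5_000) <= 20 and abs(h.s.end - 7_500) <= 20
        assert 94.0 <= h.identity <= 98.0

    def test_origin_spanning_hit_has_wraps(self):
        rng = np.random.default_rng(3)
        seg = random_seq(rng, 3_000)
        A = GenomeRecord("A", seg[1500:] + random_seq(rng, 20_000) + seg[:1500])
        B = GenomeRecord("B", random_seq(rng, 4_000) + seg + random_seq(rng, 9_000))
        hits = local_align(A, B, AlignParams(min_len=2000, min_ident=95.0))
        assert len(hits) == 1
        assert hits[0].q.wraps
        assert abs(hits[0].q.span - 3_000) <= 20

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            local_align(GenomeRecord("a", "ACGT"), GenomeRecord("b", ""), AlignParams())

    def test_degenerate_params_rejected(self):
        with pytest.raises(AlignerConfigError):
            AlignParams(k=12, min_len=8)

    def test_reverse_complement_equivariance(self):
        rng = np.random.default_rng(4)
        seg = random_seq(rng, 2_500)
        A = GenomeRecord("A", random_seq(rng, 3_000) + seg + random_seq(rng, 4_000))
        B = GenomeRecord("B", random_seq(rng, 2_000) + seg + random_seq(rng, 5_000))
        fwd = local_align(A, B, AlignParams(min_len=2000, min_ident=95.0))
        rev = local_align(
            A, GenomeRecord("B", reverse_complement(B.sequence)),
            AlignParams(min_len=2000, min_ident=95.0),
        )
        assert len(fwd) == len(rev) == 1
        assert fwd[0].orientation == "forward" and rev[0].orientation == "reverse"
        L = B.length
        # subject coordinates reflect around the sequence
        assert abs(rev[0].s.start - (L - fwd[0].s.end)) <= 2
        assert abs(rev[0].s.end - (L - fwd[0].s.start)) <= 2

    def test_rotation_equivariance_on_circles(self):
        rng = np.random.default_rng(5)
        seg = random_seq(rng, 2_500)
        A = GenomeRecord("A", random_seq(rng, 3_000) + seg + random_seq(rng, 4_000))
        B = GenomeRecord("B", random_seq(rng, 2_000) + seg + random_seq(rng, 5_000))
        params = AlignParams(min_len=2000, min_ident=95.0)
        base = {(h.q.span, round(h.identity, 1), h.orientation) for h in local_align(A, B, params)}
        for off in (1_234, 5_000):
            rot = {(h.q.span, round(h.identity, 1), h.orientation)
                   for h in local_align(A, rotate_origin(B, off), params)}
            assert rot == base

    def test_hit_table_has_twelve_columns(self):
        rng = np.random.default_rng(6)
        g = GenomeRecord("g", random_seq(rng, 5_000), circular=False)
        table = alignments_to_table(local_align(g, g, AlignParams(min_len=100, min_ident=95.0)))
        assert list(table.columns) == [
            "query", "subject", "identity", "length", "mismatches", "gap_columns",
            "q_start", "q_end", "s_start", "s_end", "orientation", "score",
        ]
        assert table.loc[0, "q_start"] == 1  # 1-based output


class TestSelfAlign:
    def test_random_sequence_has_no_qualifying_repeats(self):
        rng = np.random.default_rng(10)
        g = GenomeRecord("g", random_seq(rng, 10_000))
        assert self_align(g, AlignParams(min_len=100, min_ident=95.0)) == []
        # independent exact check on a window pair: the best off-diagonal
        # alignment of unrelated halves scores far below a 100 bp / 95% hit
        oracle = dp_oracle_align(g.sequence[:2000], g.sequence[5000:7000])
        assert oracle is None or oracle.score < 50

    def test_planted_duplicate_reported_once_in_canonical_form(self):
        rng = np.random.default_rng(11)
        core = random_seq(rng, 500)
        g = GenomeRecord("g", random_seq(rng, 3_000) + core + random_seq(rng, 4_000) + core + random_seq(rng, 2_500))
        hits = self_align(g, AlignParams(min_len=100, min_ident=95.0))
        assert len(hits) == 1
        (h,) = hits
        assert h.q.start < h.s.start
        assert h.identity == 100.0
        assert abs(h.q.span - 500) <= 5
        assert abs(h.q.start - 3_000) <= 5 and abs(h.s.start - 7_500) <= 5

    def test_inverted_copy_reported_as_reverse(self):
        rng = np.random.default_rng(12)
        core = random_seq(rng, 500)
        g = GenomeRecord(
            "g",
            random_seq(rng, 3_000) + core + random_seq(rng, 4_000)
            + reverse_complement(core) + random_seq(rng, 2_500),
        )
        hits = self_align(g, AlignParams(min_len=100, min_ident=95.0))
        assert len(hits) == 1
        assert hits[0].orientation == "reverse"


class TestDpOracle:
    def test_perfect_match(self):
        h = dp_oracle_align("ACGTACGT", "ACGTACGT")
        assert h.score == 8 and h.identity == 100.0 and h.aln_len == 8

    def test_no_alignment_above_zero(self):
        assert dp_oracle_align("AAAA", "TTTT") is None

    def test_size_cap(self):
        with pytest.raises(AlignerConfigError):
            dp_oracle_align("A" * 5001, "ACGT")

    def test_seed_extend_tracks_oracle_on_small_pairs(self):
        """Heuristic best-hit score within 5% of the exact local optimum,
        and identical identity on gap-free alignments."""
        rng = np.random.default_rng(13)
        params = AlignParams(min_len=30, min_ident=70.0)
        for _ in range(40):
            core = random_seq(rng, int(rng.integers(60, 250)))
            core_mut = mutate(rng, core, int(rng.integers(0, max(2, len(core) // 30))))
            a = random_seq(rng, int(rng.integers(0, 40))) + core + random_seq(rng, int(rng.integers(0, 40)))
            b = random_seq(rng, int(rng.integers(0, 40))) + core_mut + random_seq(rng, int(rng.integers(0, 40)))
            oracle = dp_oracle_align(a, b, params)
            hits = local_align(
                GenomeRecord("a", a, circular=False),
                GenomeRecord("b", b, circular=False),
                params,
            )
            assert hits, "heuristic found nothing where oracle aligned"
            best = max(h.score for h in hits)
            assert best >= 0.95 * oracle.score
            if oracle.n_gapcols == 0:
                top = max(hits, key=lambda h: h.score)
                if top.score == oracle.score and (
                    top.q.start, top.q.end
                ) == (oracle.q.start, oracle.q.end):
                    # same optimal alignment found -> identical identity
                    # (co-optimal alignments of equal score may differ in
                    # extent, trading terminal match/mismatch columns)
                    assert top.identity == pytest.approx(oracle.identity, abs=1e-9)
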