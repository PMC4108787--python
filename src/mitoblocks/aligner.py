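"""Pairwise local nucleotide alignment by seed-chain-extend.

This module provides the alignment engine behind every comparison in the
package: genome vs genome (synteny blocks), genome vs itself (repeats),
ORF vs genome (chimera classification) and mitogenome vs plastid
(plastid-derived sequence screening).

The heuristic pipeline is the classic one: exact k-mer seeds are matched
through a sorted index, collinear seeds are clustered along diagonals,
each cluster window is aligned base-level with edlib, and the resulting
alignment path is trimmed to its best-scoring local segment under an
affine gap score.  Circular sequences are searched across the origin by
doubling each circular axis and keeping only canonical hits (both start
coordinates below the genome length).

An exact dynamic-programming oracle (:func:`dp_oracle_align`, backed by
Biopython's ``PairwiseAligner``) is exposed for testing: on small inputs
the heuristic's best hit must come within a few percent of the optimal
local score.

Identity is defined as matched columns / total alignment columns, so gap
columns count against identity; ambiguity codes never count as matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from Bio import Align

from .genome_io import (
    CircularInterval,
    GenomeRecord,
    reverse_complement,
)

__all__ = [
    "AlignParams",
    "LocalAlignment",
    "AlignerConfigError",
    "local_align",
    "self_align",
    "dp_oracle_align",
    "alignments_to_table",
]

DP_ORACLE_SIZE_CAP = 5000


class AlignerConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    """Tunable knobs of the seed-chain-extend heuristic.

    ``min_len``/``min_ident`` are the reporting thresholds (bp of aligned
    span, percent identity); ``k`` the exact seed length; ``max_gap_chain``
    the largest seed-to-seed gap bridged while clustering; ``band`` the
    diagonal drift tolerated within one cluster.
    """

    k: int = 12
    min_len: int = 100
    min_ident: float = 90.0
    max_gap_chain: int = 100
    band: int = 75
    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -2
    pad: int = 40

    def __post_init__(self):
        if self.k < 8:
            raise AlignerConfigError("seed length k must be >= 8")
        if not (0 < self.min_ident <= 100):
            raise AlignerConfigError("min_ident must lie in (0, 100]")
        if self.min_len < self.k:
            raise AlignerConfigError("min_len must be >= k")


@dataclass(frozen=True)
class LocalAlignment:
    """One pairwise local match between a query and a subject sequence."""

    q: CircularInterval
    s: CircularInterval
    orientation: str  # "forward" | "reverse"
    identity: float
    aln_len: int
    n_mismatch: int
    n_gapcols: int
    score: int

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise AlignerConfigError(f"bad orientation {self.orientation!r}")

    @property
    def n_match(self) -> int:
        return self.aln_len - self.n_mismatch - self.n_gapcols


# ---------------------------------------------------------------------------
# encoding and seeding

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes and a validity mask (no ambiguity codes)."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    base = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = base[j : j + n]
        codes = (codes << 2) | np.where(col == 255, 0, col)
        valid &= col != 255
    return codes, valid


class SeedIndex:
    """Sorted k-mer index over a subject string (may be a doubled circle)."""

    def __init__(self, seq: str, k: int):
        self.k = k
        codes, valid = _kmer_codes(_encode(seq), k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order].astype(np.int64)

    def matches(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, subject_pos) pairs of exact k-mer matches."""
        codes, valid = _kmer_codes(_encode(seq), self.k)
        qpos_all = np.nonzero(valid)[0]
        codes = codes[qpos_all]
        lo = np.searchsorted(self.codes, codes, side="left")
        hi = np.searchsorted(self.codes, codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(qpos_all, counts)
        offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
        idx = np.arange(total) - np.repeat(offsets, counts) + np.repeat(lo, counts)
        spos = self.pos[idx]
        return qpos.astype(np.int64), spos


def _cluster_seeds(
    qpos: np.ndarray, spos: np.ndarray, k: int, max_gap: int, band: int
) -> list[tuple[int, int, int, int]]:
    """Group collinear seeds into candidate rectangles (q0, q1, s0, s1)."""
    if qpos.size == 0:
        return []
    diag = qpos - spos
    order = np.lexsort((qpos, diag))
    qpos, spos, diag = qpos[order], spos[order], diag[order]
    clusters = []
    q0 = q1 = int(qpos[0])
    s0 = s1 = int(spos[0])
    d_lo = d_hi = int(diag[0])
    for i in range(1, qpos.size):
        q, s, d = int(qpos[i]), int(spos[i]), int(diag[i])
        same_diag_band = d - d_lo <= band
        # within a diagonal band seeds are sorted by q; extend while the
        # q-gap stays bridgeable
        if same_diag_band and (d <= d_hi + band) and (q - q1 <= max_gap) and q >= q0 - max_gap:
            q0, q1 = min(q0, q), max(q1, q)
            s0, s1 = min(s0, s), max(s1, s)
            d_hi = max(d_hi, d)
        else:
            clusters.append((q0, q1 + k, s0, s1 + k))
            q0 = q1 = q
            s0 = s1 = s
            d_lo = d_hi = d
    clusters.append((q0, q1 + k, s0, s1 + k))
    # merge rectangles that overlap on both axes (same diagonal family)
    clusters.sort()
    merged: list[list[int]] = []
    for c in clusters:
        for m in merged:
            if (
                c[0] < m[1] + 1
                and c[1] > m[0]
                and c[2] < m[3] + 1
                and c[3] > m[2]
                and abs((c[0] - c[2]) - (m[0] - m[2])) <= band
            ):
                m[0], m[1] = min(m[0], c[0]), max(m[1], c[1])
                m[2], m[3] = min(m[2], c[2]), max(m[3], c[3])
                break
        else:
            merged.append(list(c))
    return [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# window alignment via edlib + local trimming

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _column_walk(cigar: str, a: str, b: str):
    """Yield per-column (op, qchar, schar) for an edlib NW path.

    edlib 'I' consumes the query, 'D' the subject.  'M' (should not occur
    with extended cigars) is resolved by character comparison.  Columns in
    which either character is an ambiguity code are demoted to mismatch.
    """
    qi = si = 0
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        for _ in range(n):
            if op == "I":
                yield "I", a[qi], None
                qi += 1
            elif op == "D":
                yield "D", None, b[si]
                si += 1
            else:
                qc, sc = a[qi], b[si]
                if qc == sc and qc in "ACGT":
                    yield "=", qc, sc
                else:
                    yield "X", qc, sc
                qi += 1
                si += 1


def _best_local_segment(cols, params: AlignParams):
    """Kadane scan over alignment columns under the affine gap score.

    Returns (start_col, end_col, score) of the best-scoring contiguous
    column range, or None if no positive-scoring segment exists.  A gap
    run is charged ``gap_open`` on its first column and ``gap_extend`` on
    every column.
    """
    best = (0.0, -1, -1)  # score, start, end (exclusive)
    run_score = 0.0
    run_start = 0
    prev_gap = False
    for i, (op, _, _) in enumerate(cols):
        if op == "=":
            sc = params.match
            prev_gap = False
        elif op == "X":
            sc = params.mismatch
            prev_gap = False
        else:
            sc = params.gap_extend + (0 if prev_gap else params.gap_open)
            prev_gap = True
        if run_score <= 0:
            run_score = sc
            run_start = i
            prev_gap = op in "ID"  # new segment: gap run restarts
        else:
            run_score += sc
        if run_score > best[0]:
            best = (run_score, run_start, i + 1)
    if best[1] < 0:
        return None
    return best[1], best[2], best[0]


def _align_window(a: str, b: str, params: AlignParams):
    """Align the query window into the subject window (infix mode, so the
    subject flanks are free), then trim to the best local segment.
    Returns (qa, qb, sa, sb, n_match, n_mismatch, n_gap, score) in window
    coordinates, or None."""
    res = edlib.align(a, b, mode="HW", task="path")
    cigar = res.get("cigar")
    if not cigar:
        return None
    s_off = res["locations"][0][0] or 0
    cols = list(_column_walk(cigar, a, b[s_off:]))
    seg = _best_local_segment(cols, params)
    if seg is None:
        return None
    c0, c1, score = seg
    qa = sum(1 for op, _, _ in cols[:c0] if op in "=XI")
    sa = sum(1 for op, _, _ in cols[:c0] if op in "=XD")
    n_match = n_mm = n_gap = 0
    qb, sb = qa, sa
    for op, _, _ in cols[c0:c1]:
        if op == "=":
            n_match += 1
            qb += 1
            sb += 1
        elif op == "X":
            n_mm += 1
            qb += 1
            sb += 1
        elif op == "I":
            n_gap += 1
            qb += 1
        else:
            n_gap += 1
            sb += 1
    if qb == qa or sb == sa:
        return None
    return qa, qb, s_off + sa, s_off + sb, n_match, n_mm, n_gap, int(round(score))


# exact affine local alignment for small windows: edlib's unit-cost edit
# path can place gaps differently from the optimal affine-scored path;
# on small windows we afford the exact Gotoh DP (vectorized per row,
# with pointer matrices for traceback)

EXACT_WINDOW_CAP = 400


def _gotoh_window(a: str, b: str, params: AlignParams):
    """Exact best local alignment of two windows under the affine score.
    Same return contract as :func:`_align_window`."""
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return None
    ea, eb = _encode(a), _encode(b)
    go, ge = params.gap_open, params.gap_extend
    sub_match, sub_mm = params.match, params.mismatch
    NEG = -(10**9)

    ptr0 = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 3 F
    eflag = np.zeros((m + 1, n + 1), dtype=bool)
    e_start = np.zeros((m + 1, n + 1), dtype=np.int32)
    f_start = np.zeros((m + 1, n + 1), dtype=np.int32)

    H_prev = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    f_start_row = np.zeros(n + 1, dtype=np.int32)
    jidx = np.arange(n + 1, dtype=np.int64)
    best = (0, 0, 0)
    for i in range(1, m + 1):
        # vertical gaps (consume query rows)
        f_open = H_prev + go + ge
        f_cont = F + ge
        new_from_open = f_open >= f_cont
        F = np.where(new_from_open, f_open, f_cont)
        f_start_row = np.where(new_from_open, i - 1, f_start_row).astype(np.int32)

        match_col = (eb == ea[i - 1]) & (eb != 255) & (ea[i - 1] != 255)
        sub = np.where(match_col, sub_match, sub_mm)
        H0 = np.zeros(n + 1, dtype=np.int64)
        H0[1:] = np.maximum(H_prev[:-1] + sub, 0)
        H0 = np.maximum(H0, F)
        H0 = np.maximum(H0, 0)
        p0 = np.zeros(n + 1, dtype=np.uint8)
        p0[1:] = np.where(H_prev[:-1] + sub == H0[1:], 1, 0).astype(np.uint8)
        p0 = np.where((F == H0) & (H0 > 0) & (p0 == 0), 3, p0).astype(np.uint8)

        # horizontal gaps via prefix-max over H0 anchors
        vals = H0 - ge * jidx
        cummax = np.maximum.accumulate(vals)
        achieve = np.where(vals == cummax, jidx, 0)
        anchor = np.maximum.accumulate(achieve)
        E = np.full(n + 1, NEG, dtype=np.int64)
        E[1:] = go + ge * jidx[1:] + cummax[:-1]
        e_anchor = np.zeros(n + 1, dtype=np.int64)
        e_anchor[1:] = anchor[:-1]

        H = np.maximum(H0, E)
        use_e = E > H0
        ptr0[i] = p0
        eflag[i] = use_e
        e_start[i] = e_anchor
        f_start[i] = f_start_row

        j_best = int(np.argmax(H))
        if H[j_best] > best[0]:
            best = (int(H[j_best]), i, j_best)
        H_prev = H
    score, bi, bj = best
    if score <= 0:
        return None

    # traceback
    i, j = bi, bj
    n_match = n_mm = n_gap = 0
    after_e_jump = False
    while True:
        if not after_e_jump and eflag[i, j]:
            j0 = int(e_start[i, j])
            n_gap += j - j0
            j = j0
            after_e_jump = True
            continue
        p = ptr0[i, j]
        after_e_jump = False
        if p == 0:
            break
        if p == 1:
            qc, sc = a[i - 1], b[j - 1]
            if qc == sc and qc in "ACGT":
                n_match += 1
            else:
                n_mm += 1
            i -= 1
            j -= 1
        else:  # vertical gap run
            i0 = int(f_start[i, j])
            n_gap += i - i0
            i = i0
    qa, sa = i, j
    if bi == qa or bj == sa:
        return None
    return qa, bi, sa, bj, n_match, n_mm, n_gap, score


# ---------------------------------------------------------------------------
# public entry points


def _axis(genome: GenomeRecord) -> tuple[str, int, bool]:
    """Search axis for a record: doubled when circular."""
    if genome.circular and genome.length > 1:
        return genome.sequence + genome.sequence, genome.length, True
    return genome.sequence, genome.length, False


def _make_hit(qid, sid, LQ, LS, qa, qb, sa, sb, orientation, stats) -> LocalAlignment | None:
    n_match, n_mm, n_gap, score = stats
    # canonicalize onto [0, L) starts
    if qa >= LQ:
        qa, qb = qa - LQ, qb - LQ
    if sa >= LS:
        sa, sb = sa - LS, sb - LS
    if qa >= LQ or sa >= LS or qb - qa > LQ or sb - sa > LS:
        return None
    aln_len = n_match + n_mm + n_gap
    identity = 100.0 * n_match / aln_len if aln_len else 0.0
    q = CircularInterval(qid, qa, qb, "+", wraps=qb > LQ)
    s = CircularInterval(sid, sa, sb, "+", wraps=sb > LS)
    return LocalAlignment(q, s, orientation, identity, aln_len, n_mm, n_gap, score)


def _collect_hits(
    A: GenomeRecord,
    B: GenomeRecord,
    params: AlignParams,
    orientation: str,
    self_mode: bool,
    index: SeedIndex | None = None,
) -> list[LocalAlignment]:
    qseq, LQ, _ = _axis(A)
    if orientation == "forward":
        sseq_raw, LS, _ = _axis(B)
    else:
        sseq_raw, LS, _ = _axis(GenomeRecord(B.id, reverse_complement(B.sequence), B.circular))
    idx = index if index is not None else SeedIndex(sseq_raw, params.k)
    qpos, spos = idx.matches(qseq)
    if self_mode and orientation == "forward":
        keep = (qpos - spos) % LQ != 0
        qpos, spos = qpos[keep], spos[keep]
    hits = []
    slen = len(sseq_raw)
    for q0, q1, s0, s1 in _cluster_seeds(qpos, spos, params.k, params.max_gap_chain, params.band):
        # pad both axes by the same amount so the windows stay the same
        # size: an asymmetric pad would force spurious gaps in the infix
        # alignment and fragment the homology edge
        pad_l = min(params.pad, q0, s0)
        pad_r = min(params.pad, len(qseq) - q1, slen - s1)
        q0, s0 = q0 - pad_l, s0 - pad_l
        q1, s1 = q1 + pad_r, s1 + pad_r
        # never align more than one full turn of a circle
        q1 = min(q1, q0 + LQ)
        s1 = min(s1, s0 + LS)
        if q1 - q0 < params.k or s1 - s0 < params.k:
            continue
        res = _align_window(qseq[q0:q1], sseq_raw[s0:s1], params)
        if res is None:
            continue
        # refine small windows with the exact affine DP, but only when the
        # fast edit-distance screen suggests a reportable hit — random
        # seed-collision windows are discarded cheaply
        if q1 - q0 <= EXACT_WINDOW_CAP and s1 - s0 <= EXACT_WINDOW_CAP:
            qa_, qb_, sa_, sb_, n_match_, n_mm_, n_gap_, _ = res
            cols_ = n_match_ + n_mm_ + n_gap_
            ident_ = 100.0 * n_match_ / cols_ if cols_ else 0.0
            if (
                min(qb_ - qa_, sb_ - sa_) >= min(params.min_len, 2 * params.k)
                and ident_ >= params.min_ident - 10.0
            ):
                refined = _gotoh_window(qseq[q0:q1], sseq_raw[s0:s1], params)
                if refined is not None:
                    res = refined
        qa, qb, sa, sb, n_match, n_mm, n_gap, score = res
        qa, qb, sa, sb = q0 + qa, q0 + qb, s0 + sa, s0 + sb
        if orientation == "reverse":
            # map back onto the forward strand of the subject axis
            sa, sb = slen - sb, slen - sa
        hit = _make_hit(A.id, B.id, LQ, LS, qa, qb, sa, sb, orientation,
                        (n_match, n_mm, n_gap, score))
        if hit is not None:
            hits.append(hit)
    return hits


def _passes(h: LocalAlignment, params: AlignParams) -> bool:
    return (
        min(h.q.span, h.s.span) >= params.min_len
        and h.identity >= params.min_ident
    )


def _circular_overlap(x: CircularInterval, y: CircularInterval, L: int) -> int:
    return sum(
        max(0, min(e0, e1) - max(s0, s1))
        for s0, e0 in x.segments(L)
        for s1, e1 in y.segments(L)
    )


def _dedupe(hits: list[LocalAlignment], LQ: int, LS: int) -> list[LocalAlignment]:
    seen = {}
    for h in hits:
        key = (h.q.start, h.q.end, h.s.start, h.s.end, h.orientation)
        if key not in seen or h.score > seen[key].score:
            seen[key] = h
    out = list(seen.values())
    # drop hits (near-)contained in a longer hit: >=90% of both footprints
    # already covered (mod L) means the same underlying match was found
    # twice, e.g. the two mirror discoveries of an inverted repeat or a
    # rediscovery across the origin
    def _ov(x, y, L):
        return _circular_overlap(x, y, L) / x.span

    out.sort(key=lambda h: (-h.aln_len, h.q.start, h.s.start))
    kept: list[LocalAlignment] = []
    for h in out:
        redundant = any(
            g.orientation == h.orientation
            and _ov(h.q, g.q, LQ) >= 0.9
            and _ov(h.s, g.s, LS) >= 0.9
            for g in kept
        )
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.q.start, h.s.start))
    return kept


def local_align(
    A: GenomeRecord,
    B: GenomeRecord,
    params: AlignParams | None = None,
    _subject_indexes: tuple[SeedIndex, SeedIndex] | None = None,
) -> list[LocalAlignment]:
    """All maximal local alignments of A (query) against B (subject).

    Both orientations are searched; circular inputs are searched across
    the origin.  Hits are filtered by ``params.min_len`` (aligned span on
    the shorter side) and ``params.min_ident``, deduplicated and sorted
    by query start.

    ``_subject_indexes`` optionally carries prebuilt (forward, reverse)
    seed indexes of B so that many queries can reuse them.
    """
    params = params or AlignParams()
    if not A.sequence or not B.sequence:
        raise AlignerConfigError("cannot align empty sequences")
    fwd_idx = rev_idx = None
    if _subject_indexes is not None:
        fwd_idx, rev_idx = _subject_indexes
    hits = _collect_hits(A, B, params, "forward", self_mode=False, index=fwd_idx)
    hits += _collect_hits(A, B, params, "reverse", self_mode=False, index=rev_idx)
    hits = [h for h in hits if _passes(h, params)]
    return _dedupe(hits, A.length, B.length)


def build_subject_indexes(B: GenomeRecord, params: AlignParams) -> tuple[SeedIndex, SeedIndex]:
    """Prebuild forward/reverse seed indexes of a subject genome."""
    sseq, _, _ = _axis(B)
    rseq, _, _ = _axis(GenomeRecord(B.id, reverse_complement(B.sequence), B.circular))
    return SeedIndex(sseq, params.k), SeedIndex(rseq, params.k)


def self_align(A: GenomeRecord, params: AlignParams | None = None) -> list[LocalAlignment]:
    """Within-genome repeats: A aligned against itself, with the trivial
    full-length identity removed and each pair reported once in canonical
    (q.start < s.start) form."""
    params = params or AlignParams()
    hits = _collect_hits(A, A, params, "forward", self_mode=True)
    hits += _collect_hits(A, A, params, "reverse", self_mode=True)
    canon = []
    for h in hits:
        if h.q.start == h.s.start and h.q.end == h.s.end:
            continue  # palindromic self-hit or residual trivial match
        if h.q.start > h.s.start or (h.q.start == h.s.start and h.q.end > h.s.end):
            h = replace(h, q=h.s, s=h.q)
        canon.append(h)
    canon = [h for h in canon if _passes(h, params)]
    return _dedupe(canon, A.length, A.length)


# ---------------------------------------------------------------------------
# exact oracle


def dp_oracle_align(a: str, b: str, params: AlignParams | None = None) -> LocalAlignment | None:
    """Exact best-scoring forward local alignment by full dynamic
    programming (Biopython ``PairwiseAligner``), for use as a test oracle.

    Inputs are capped at 5 kb each (quadratic cost).  Returns None when no
    alignment scores above zero.
    """
    params = params or AlignParams()
    if len(a) > DP_ORACLE_SIZE_CAP or len(b) > DP_ORACLE_SIZE_CAP:
        raise AlignerConfigError(f"oracle inputs capped at {DP_ORACLE_SIZE_CAP} bp")
    if not a or not b:
        return None
    pa = Align.PairwiseAligner(
        mode="local",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap_open + params.gap_extend,
        extend_gap_score=params.gap_extend,
    )
    score = pa.score(a, b)
    if score <= 0:
        return None
    alns = pa.align(a, b)
    aln = alns[0]
    blocks_q, blocks_s = aln.aligned
    qa, qb = int(blocks_q[0][0]), int(blocks_q[-1][1])
    sa, sb = int(blocks_s[0][0]), int(blocks_s[-1][1])
    counts = aln.counts()
    n_match = counts.identities
    n_mm = counts.mismatches
    n_gap = counts.internal_gaps
    aln_len = n_match + n_mm + n_gap
    identity = 100.0 * n_match / aln_len if aln_len else 0.0
    return LocalAlignment(
        q=CircularInterval("query", qa, qb),
        s=CircularInterval("subject", sa, sb),
        orientation="forward",
        identity=identity,
        aln_len=aln_len,
        n_mismatch=n_mm,
        n_gapcols=n_gap,
        score=int(score),
    )


# ---------------------------------------------------------------------------
# export


def alignments_to_table(hits: list[LocalAlignment]) -> "pandas.DataFrame":
    """12-column hit table (1-based inclusive output coordinates)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "query": h.q.genome_id,
                "subject": h.s.genome_id,
                "identity": round(h.identity, 1),
                "length": h.aln_len,
                "mismatches": h.n_mismatch,
                "gap_columns": h.n_gapcols,
                "q_start": h.q.start + 1,
                "q_end": h.q.end,
                "s_start": h.s.start + 1,
                "s_end": h.s.end,
                "orientation": h.orientation,
                "score": h.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "identity", "length", "mismatches",
            "gap_columns", "q_start", "q_end", "s_start", "s_end",
            "orientation", "score",
        ],
    )
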