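"""ORF discovery, comparative classification and the CMS-candidate screen.

Cytoplasmic male sterility genes in plant mitochondria are typically
novel chimeric open reading frames: fusions of fragments from several
genomic loci, carrying a transmembrane segment, sitting at the edge of
rearranged, line-specific sequence next to recombination-active repeats.
This module implements each leg of that screen:

* :func:`find_orfs` — six-frame ORF calling on a circular genome,
  including origin-spanning frames (hypothetical proteins strictly
  longer than ``min_aa`` residues; one ORF per (frame, stop codon), the
  longest ATG-initiated reading).
* :func:`classify_orfs` — compare each ORF against the counterpart
  genome and call it identical / polymorphic / chimeric / unique from
  alignment coverage and the number of source loci.
* :func:`predict_tm` — Kyte-Doolittle sliding-window hydropathy as a
  transmembrane proxy (window 19, mean threshold 1.6).
* :func:`screen_candidates` — intersect the chimeric/unique calls with
  proximity to syntenic-block edges and repeats and the TM flag.
* :func:`compare_genes` — per-gene comparison of annotated coding
  sequences between two lines (SNPs with codon context and synonymy,
  in-frame indels, terminal rearrangement calls, outgroup polarity and
  a C-to-U editing caveat flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .aligner import AlignParams, LocalAlignment, build_subject_indexes, local_align
from .genome_io import (
    CircularInterval,
    FeatureRecord,
    GenomeRecord,
    interval_interval_distance,
    reverse_complement,
)
from .repeats import RepeatMatch
from .synteny import SyntenicBlock

__all__ = [
    "OrfRecord",
    "GenePolymorphism",
    "CandidateReport",
    "find_orfs",
    "classify_orf",
    "classify_orfs",
    "predict_tm",
    "screen_candidates",
    "compare_genes",
    "KYTE_DOOLITTLE",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

ORF_CLASSES = ("known", "identical", "polymorphic", "chimeric", "unique")


@dataclass
class OrfRecord:
    name: str
    interval: CircularInterval
    strand: str
    protein: str
    aa_len: int
    overlaps_known_gene: bool = False
    orf_class: str | None = None
    tm: bool = False
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    dist_block_edge: int | None = None
    dist_repeat: int | None = None

    @property
    def nt_len(self) -> int:
        return self.interval.span


@dataclass(frozen=True)
class GenePolymorphism:
    gene: str
    site: int  # 1-based start of the first affected codon in genome A's CDS
    kind: str  # SNP_synonymous | SNP_nonsynonymous | inframe_indel |
    #            rearranged_3prime | rearranged_5prime
    ref_codon: str
    alt_codon: str
    aa_change: str
    outgroup_state: str = "unknown"  # matches_first | matches_second | unknown
    editing_sensitive: bool = False


@dataclass
class CandidateRow:
    orf: OrfRecord
    is_chimeric_or_unique: bool
    near_block_edge: bool
    near_repeat: bool
    has_tm: bool

    @property
    def is_candidate(self) -> bool:
        return (
            self.is_chimeric_or_unique
            and self.near_block_edge
            and self.near_repeat
            and self.has_tm
        )


@dataclass
class CandidateReport:
    genome_id: str
    rows: list[CandidateRow]
    final_candidates: list[str]


# ---------------------------------------------------------------------------
# ORF discovery


def _scan_strand(seq2: str, L: int, strand: str, min_aa: int):
    """Scan the three frames of one strand of a doubled circular sequence
    (or the plain sequence for a linear genome).  Yields raw (start, end,
    strand, protein) with coordinates on the forward doubled axis."""
    n = len(seq2)
    for frame in range(3):
        atg = None
        pos = frame
        while pos + 3 <= n:
            codon = seq2[pos : pos + 3]
            if atg is None and codon == "ATG":
                atg = pos
            if codon in STOP_CODONS:
                if atg is not None:
                    start, end = atg, pos + 3
                    aa_len = (end - start) // 3 - 1
                    if aa_len > min_aa and end - start <= L:
                        yield start, end, strand, aa_len
                atg = None
            pos += 3


def _orf_forward_coords(start, end, strand, L, circular):
    """Map a raw ORF on the scanned axis to canonical forward-strand
    genome coordinates."""
    if strand == "+":
        fs, fe = start, end
    else:
        axis_len = 2 * L if circular else L
        fs, fe = axis_len - end, axis_len - start
    if circular and fs >= L:
        fs, fe = fs - L, fe - L
    return fs, fe


def find_orfs(
    genome: GenomeRecord,
    min_aa: int = 100,
    features: list[FeatureRecord] | None = None,
) -> list[OrfRecord]:
    """Six-frame ORF scan; strictly greater than ``min_aa`` residues.

    ORFs run ATG..stop under the standard genetic code; per (frame, stop)
    only the longest ATG-initiated reading is reported.  On circular
    genomes origin-spanning ORFs are found by scanning the doubled
    sequence and keeping the canonical copy.  ORFs overlapping an
    annotated protein or rRNA gene are flagged ``overlaps_known_gene``
    (they are excluded from novel-ORF counts downstream, not dropped).

    Names follow the convention orf<aa-length>, with letter suffixes
    (orf113a, orf113b, ...) when several ORFs share a length.
    """
    L = genome.length
    seqs = {
        "+": genome.sequence + genome.sequence if genome.circular else genome.sequence,
    }
    seqs["-"] = reverse_complement(seqs["+"])
    raw = []
    for strand, s2 in seqs.items():
        for start, end, st, aa_len in _scan_strand(s2, L, strand, min_aa):
            fs, fe = _orf_forward_coords(start, end, st, L, genome.circular)
            raw.append((fs, fe, st))
    seen = set()
    orfs = []
    known = [
        f.interval
        for f in (features or [])
        if f.kind in ("protein", "rRNA")
    ]
    for fs, fe, strand in sorted(set(raw)):
        key = (fs, fe, strand)
        if key in seen:
            continue
        seen.add(key)
        iv = CircularInterval(genome.id, fs, fe, strand, wraps=fe > L)
        nt = genome.fetch_interval(iv)
        protein = str(Seq(nt).translate(table=1)).rstrip("*")
        if not protein.startswith("M"):
            continue
        overlaps = any(iv.overlaps(k, L) for k in known)
        orfs.append(
            OrfRecord(
                name="",
                interval=iv,
                strand=strand,
                protein=protein,
                aa_len=len(protein),
                overlaps_known_gene=overlaps,
            )
        )
    # stable naming: sort by genome position, letter the length collisions
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    by_len: dict[int, list[OrfRecord]] = {}
    for o in orfs:
        by_len.setdefault(o.aa_len, []).append(o)
    for aa, group in by_len.items():
        if len(group) == 1:
            group[0].name = f"orf{aa}"
        else:
            for i, o in enumerate(group):
                o.name = f"orf{aa}{chr(ord('a') + i)}"
    return orfs


# ---------------------------------------------------------------------------
# comparative classification


def _orf_alignments(orf, genome, counterpart, params, indexes):
    query = GenomeRecord(
        f"{orf.name or 'orf'}", genome.fetch_interval(orf.interval), circular=False
    )
    return local_align(query, counterpart, params, _subject_indexes=indexes)


def _count_loci(hits: list[LocalAlignment], L: int, locus_gap: int = 2000) -> int:
    """Distinct source loci on the counterpart: hit clusters separated by
    more than ``locus_gap`` bp or lying in opposite orientations."""
    if not hits:
        return 0
    loci = []
    for h in sorted(hits, key=lambda h: h.s.start):
        placed = False
        for locus in loci:
            if locus["orient"] == h.orientation and (
                h.s.start <= locus["end"] + locus_gap and h.s.end >= locus["start"] - locus_gap
            ):
                locus["start"] = min(locus["start"], h.s.start)
                locus["end"] = max(locus["end"], h.s.end)
                placed = True
                break
        if not placed:
            loci.append({"start": h.s.start, "end": h.s.end, "orient": h.orientation})
    return len(loci)


def classify_orf(
    orf: OrfRecord,
    genome: GenomeRecord,
    counterpart: GenomeRecord,
    params: AlignParams | None = None,
    _indexes=None,
    coverage_identical: float = 99.0,
    coverage_polymorphic: float = 90.0,
    coverage_unique: float = 40.0,
) -> str:
    """Comparative class of one ORF against the counterpart genome.

    identical    single locus, >=99% coverage, every hit at 100% identity
    polymorphic  single locus, >=90% coverage, with mismatches or indels
    chimeric     >=2 loci (separated by >2 kb or opposite orientations)
                 jointly covering >=40%, or a single locus covering
                 40-90% with the remainder unmatched
    unique       <40% coverage
    """
    params = params or AlignParams(k=11, min_len=30, min_ident=80.0, max_gap_chain=60)
    hits = _orf_alignments(orf, genome, counterpart, params, _indexes)
    from .genome_io import union_length

    nt_len = orf.nt_len
    covered = union_length([h.q for h in hits], nt_len) if hits else 0
    coverage = 100.0 * covered / nt_len
    n_loci = _count_loci(hits, counterpart.length)
    if coverage < coverage_unique:
        return "unique"
    if n_loci >= 2:
        return "chimeric"
    if coverage >= coverage_identical and all(h.identity == 100.0 for h in hits):
        return "identical"
    if coverage >= coverage_polymorphic:
        return "polymorphic"
    return "chimeric"


def classify_orfs(
    orfs: list[OrfRecord],
    genome: GenomeRecord,
    counterpart: GenomeRecord,
    params: AlignParams | None = None,
) -> None:
    """Classify many ORFs in place, reusing one seed index of the
    counterpart genome."""
    params = params or AlignParams(k=11, min_len=30, min_ident=80.0, max_gap_chain=60)
    indexes = build_subject_indexes(counterpart, params)
    for orf in orfs:
        orf.orf_class = (
            "known"
            if orf.overlaps_known_gene
            else classify_orf(orf, genome, counterpart, params, _indexes=indexes)
        )


# ---------------------------------------------------------------------------
# transmembrane prediction


def predict_tm(
    protein: str, window: int = 19, threshold: float = 1.6
) -> tuple[bool, list[tuple[int, int]]]:
    """Kyte-Doolittle sliding-window hydropathy.

    A TM segment is a maximal run of window centers whose mean hydropathy
    meets ``threshold``; segments are returned as 0-based half-open
    residue index ranges of the window centers.  Proteins shorter than
    the window are never called TM.
    """
    n = len(protein)
    if n < window:
        return False, []
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    hot = means >= threshold
    segments = []
    start = None
    offset = window // 2
    for i, h in enumerate(hot):
        if h and start is None:
            start = i
        elif not h and start is not None:
            segments.append((start + offset, i + offset))
            start = None
    if start is not None:
        segments.append((start + offset, hot.size + offset))
    return bool(segments), segments


# ---------------------------------------------------------------------------
# candidate screen


def screen_candidates(
    orfs: list[OrfRecord],
    blocks: list[SyntenicBlock],
    repeats: list[RepeatMatch],
    genome: GenomeRecord,
    max_dist: int = 2000,
    extra: list[OrfRecord] | None = None,
) -> CandidateReport:
    """The four-criterion CMS-candidate screen.

    Novel ORFs classified chimeric or unique are tested for proximity
    (circular distance, 0 when overlapping) to the nearest syntenic-block
    placement edge and the nearest repeat copy, and for a predicted TM
    segment.  ``extra`` injects known genes (e.g. a truncated atp6 copy)
    into the same screen even though they are not novel ORFs.  The final
    candidates are the entries with all four flags true.
    """
    L = genome.length
    edge_points = []
    for b in blocks:
        for p in b.on(genome.id):
            edge_points.append(p.interval.start % L)
            edge_points.append((p.interval.end - 1) % L)
    repeat_ivs = [r.a for r in repeats] + [r.b for r in repeats]

    rows = []
    screened = list(orfs) + list(extra or [])
    injected = {id(o) for o in (extra or [])}
    for orf in screened:
        chim = orf.orf_class in ("chimeric", "unique") or id(orf) in injected
        iv = orf.interval
        d_edge = (
            min(_interval_point_dist(iv, pt, L) for pt in edge_points)
            if edge_points
            else None
        )
        d_rep = (
            min(interval_interval_distance(iv, r, L) for r in repeat_ivs)
            if repeat_ivs
            else None
        )
        if not orf.tm_segments and not orf.tm:
            orf.tm, orf.tm_segments = predict_tm(orf.protein)
        orf.dist_block_edge = d_edge
        orf.dist_repeat = d_rep
        rows.append(
            CandidateRow(
                orf=orf,
                is_chimeric_or_unique=chim,
                near_block_edge=d_edge is not None and d_edge <= max_dist,
                near_repeat=d_rep is not None and d_rep <= max_dist,
                has_tm=orf.tm,
            )
        )
    final = [r.orf.name for r in rows if r.is_candidate]
    return CandidateReport(genome_id=genome.id, rows=rows, final_candidates=final)


def _interval_point_dist(iv: CircularInterval, pos: int, L: int) -> int:
    from .genome_io import interval_point_distance

    return interval_point_distance(iv, pos, L)


# ---------------------------------------------------------------------------
# annotated gene comparison


def _left_normalize(a_gapped: list[str], b_gapped: list[str]) -> None:
    """Shift every gap run to its leftmost equivalent column (in place).

    A run of gaps in one row may move one column left whenever the letter
    row reads the same character before the run and at its last column;
    repeating to a fixed point gives the canonical left-aligned indel
    placement (the convention used for reporting indel sites).
    """
    for gaps, letters in ((a_gapped, b_gapped), (b_gapped, a_gapped)):
        changed = True
        while changed:
            changed = False
            i = 0
            n = len(gaps)
            while i < n:
                if gaps[i] != "-":
                    i += 1
                    continue
                j = i
                while j < n and gaps[j] == "-":
                    j += 1
                if i > 0 and gaps[i - 1] != "-" and letters[i - 1] == letters[j - 1]:
                    gaps[j - 1] = gaps[i - 1]
                    gaps[i - 1] = "-"
                    changed = True
                    i = max(i - 1, 0)
                else:
                    i = j


def _global_align(a: str, b: str) -> tuple[list[str], list[str]]:
    pa = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-8,
        extend_gap_score=-1,
    )
    aln = pa.align(a, b)[0]
    a_g, b_g = list(str(aln[0])), list(str(aln[1]))
    _left_normalize(a_g, b_g)
    return a_g, b_g


def _codon_span_string(seq: str, codon_start0: int, codon_end0: int) -> str:
    return seq[codon_start0:codon_end0]


def _translate(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate(table=1)) if nt else ""


def _apply_ctu(s: str) -> str:
    return s.replace("C", "T")


def compare_genes(
    genes_a: list[tuple[FeatureRecord, str]],
    genes_b: list[tuple[FeatureRecord, str]],
    outgroup: list[tuple[FeatureRecord, str]] | None = None,
    min_tail: int = 30,
) -> tuple[list[GenePolymorphism], list[str]]:
    """Compare annotated coding sequences between two lines, gene by gene.

    Genes are matched by name; sequences must be supplied in coding
    orientation.  Returns (polymorphisms, skipped_gene_names).

    Substitutions are reported per affected codon run with the codon
    context of both alleles and a synonymous/non-synonymous call; indels
    whose length is a multiple of three are in-frame indels.  When the
    locally alignable region of a gene stops short of either terminus by
    at least ``min_tail`` bp, a rearrangement call is emitted for that
    side.  Outgroup sequences, when given, polarize each polymorphic
    site.  Non-synonymous substitutions whose amino-acid difference would
    vanish if every polymorphic C were read as U are flagged
    ``editing_sensitive`` (the C-to-U editing caveat).
    """
    a_by_name = {f.name: s.upper() for f, s in genes_a}
    b_by_name = {f.name: s.upper() for f, s in genes_b}
    out_by_name = {f.name: s.upper() for f, s in (outgroup or [])}
    skipped = sorted(set(a_by_name) ^ set(b_by_name))
    results: list[GenePolymorphism] = []
    for name in sorted(set(a_by_name) & set(b_by_name)):
        results.extend(
            _compare_one(name, a_by_name[name], b_by_name[name],
                         out_by_name.get(name), min_tail)
        )
    return results, skipped


def _compare_one(name, a, b, out_seq, min_tail) -> list[GenePolymorphism]:
    if a == b:
        return []
    results = []
    # rearranged terminal regions: the best local alignment stops short of
    # a gene end when the remainder shares no similarity
    pa_local = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-5, extend_gap_score=-2,
    )
    aln = pa_local.align(a, b)[0]
    qa, qb = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    re5 = qa >= min_tail
    re3 = len(a) - qb >= min_tail
    if re5:
        results.append(
            GenePolymorphism(
                gene=name, site=qa + 1, kind="rearranged_5prime",
                ref_codon="", alt_codon="", aa_change="",
            )
        )
    if re3:
        results.append(
            GenePolymorphism(
                gene=name, site=qb, kind="rearranged_3prime",
                ref_codon="", alt_codon="", aa_change="",
            )
        )
    # variant calls from the full-gene global alignment, excluding a
    # margin around rearrangement breakpoints (boundary artifacts)
    a_lo = qa + 45 if re5 else 0
    a_hi = qb - 45 if re3 else len(a)

    out_g = None
    if out_seq is not None:
        out_g = pa_local.align(a, out_seq)[0]

    a_g, b_g = _global_align(a, b)
    cols = list(zip(a_g, b_g))
    apos = bpos = 0
    runs = []  # (kind, a_start, a_end, b_start, b_end) raw difference runs
    i = 0
    n_cols = len(cols)
    while i < n_cols:
        ca, cb = cols[i]
        if ca == cb:
            apos += 1
            bpos += 1
            i += 1
            continue
        if ca != "-" and cb != "-":
            a0, b0 = apos, bpos
            while i < n_cols and cols[i][0] != "-" and cols[i][1] != "-" and cols[i][0] != cols[i][1]:
                apos += 1
                bpos += 1
                i += 1
            runs.append(("sub", a0, apos, b0, bpos))
        elif cb == "-":
            a0 = apos
            while i < n_cols and cols[i][1] == "-":
                apos += 1
                i += 1
            runs.append(("ins_a", a0, apos, bpos, bpos))
        else:
            b0 = bpos
            while i < n_cols and cols[i][0] == "-":
                bpos += 1
                i += 1
            runs.append(("ins_b", apos, apos, b0, bpos))
    runs = [r for r in runs if r[1] >= a_lo and r[2] <= a_hi]

    for kind, a0, a1, b0, b1 in runs:
        codon0 = (a0 // 3) * 3
        if kind == "sub":
            codon1 = ((a1 - 1) // 3 + 1) * 3
            # frame of B tracked via offset: b-coordinates of the same codons
            shift = b0 - a0
            ref_ctx = a[codon0:codon1]
            alt_ctx = b[codon0 + shift : codon1 + shift]
            aa_ref = _translate(ref_ctx)
            aa_alt = _translate(alt_ctx)
            synonymous = aa_ref == aa_alt
            editing = False
            if not synonymous:
                if _translate(_apply_ctu_at(ref_ctx, alt_ctx)) == _translate(
                    _apply_ctu_at(alt_ctx, ref_ctx)
                ):
                    editing = True
            results.append(
                GenePolymorphism(
                    gene=name,
                    site=codon0 + 1,
                    kind="SNP_synonymous" if synonymous else "SNP_nonsynonymous",
                    ref_codon=ref_ctx,
                    alt_codon=alt_ctx,
                    aa_change=f"{aa_ref}→{aa_alt}",
                    outgroup_state=_outgroup_state(out_g, a, a0, a1, ref_ctx, alt_ctx,
                                                   codon0, codon1, shift, b),
                    editing_sensitive=editing,
                )
            )
        else:
            ins_len = (a1 - a0) if kind == "ins_a" else (b1 - b0)
            if ins_len % 3 != 0:
                continue  # frame-disrupting indel: covered by rearrangement calls
            if kind == "ins_a":
                codon1 = ((a1 - 1) // 3 + 1) * 3 if a1 > a0 else codon0 + 3
                ref_ctx = a[codon0:codon1]
                # B lacks the run: context is the codons of A minus the run
                alt_ctx = a[codon0:a0] + a[a1:codon1]
            else:
                codon1 = codon0 + 3
                ref_ctx = a[codon0:codon1]
                alt_ctx = b[(b0 - (a0 - codon0)) : b1 + (codon1 - a0)]
            aa_ref = _translate(ref_ctx)
            aa_alt = _translate(alt_ctx)
            results.append(
                GenePolymorphism(
                    gene=name,
                    site=codon0 + 1,
                    kind="inframe_indel",
                    ref_codon=ref_ctx,
                    alt_codon=alt_ctx,
                    aa_change=f"{aa_ref}→{aa_alt}",
                    outgroup_state=_outgroup_state_indel(out_g, a, ref_ctx, alt_ctx, codon0),
                )
            )
    return results


def _apply_ctu_at(target: str, other: str) -> str:
    """Apply C->U (C->T) editing only at positions where the alleles differ."""
    out = list(target)
    for i, (x, y) in enumerate(zip(target, other)):
        if x != y and x == "C":
            out[i] = "T"
    return "".join(out)


def _aligned_outgroup_window(aln_out, a0: int, a1: int) -> str | None:
    """Outgroup characters aligned to gene-A positions [a0, a1); None when
    any position is unaligned."""
    if aln_out is None:
        return None
    qa_blocks, sa_blocks = aln_out.aligned
    chars = []
    for pos in range(a0, a1):
        hit = None
        for (qs, qe), (ss, se) in zip(qa_blocks, sa_blocks):
            if qs <= pos < qe:
                hit = ss + (pos - qs)
                break
        if hit is None:
            return None
        chars.append(str(aln_out.query[hit]))
    return "".join(chars)


def _outgroup_state(aln_out, a, a0, a1, ref_ctx, alt_ctx, codon0, codon1, shift, b):
    win = _aligned_outgroup_window(aln_out, codon0, codon1)
    if win is None:
        return "unknown"
    if win == ref_ctx:
        return "matches_first"
    if win == alt_ctx:
        return "matches_second"
    return "unknown"


def _outgroup_state_indel(aln_out, a, ref_ctx, alt_ctx, codon0):
    win = _aligned_outgroup_window(aln_out, codon0, codon0 + len(ref_ctx))
    if win is None:
        return "unknown"
    if win == ref_ctx:
        return "matches_first"
    return "unknown"
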