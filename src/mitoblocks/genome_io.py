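"""Sequence/annotation I/O and the circular-coordinate model.

Plant mitochondrial "master circle" genomes are circular molecules with an
arbitrary sequence origin.  Every other module in this package works with
the types defined here: :class:`GenomeRecord` (a named, usually circular,
nucleotide sequence), :class:`CircularInterval` (a 0-based half-open
interval that may wrap across the origin) and :class:`FeatureRecord`
(an annotated gene).

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  An interval that crosses the
origin is stored with ``start < L`` and ``end <= 2 * L`` on a virtual
doubled axis (``wraps`` is then true); exactly one such canonical
representation is allowed.  Reports and GFF3 output emit 1-based inclusive
coordinates; BED output stays 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "CircularInterval",
    "FeatureRecord",
    "read_genome",
    "write_genome",
    "read_features",
    "write_features_bed",
    "write_features_gff3",
    "circular_distance",
    "rotate_origin",
    "rotate_interval",
    "reverse_complement",
    "revcomp_genome",
    "revcomp_interval",
    "merge_intervals",
    "union_length",
    "complement_intervals",
    "interval_point_distance",
    "interval_interval_distance",
]

FEATURE_KINDS = ("protein", "rRNA", "tRNA", "orf")


class GenomeIOError(ValueError):
    """Raised for malformed or inconsistent sequence/annotation input."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence, circular by default.

    The sequence is stored uppercase; IUPAC ambiguity codes are preserved
    verbatim (they never count as matches during alignment and never as
    G/C in GC content).
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.id:
            raise GenomeIOError("genome id must be non-empty")
        if not self.sequence:
            raise GenomeIOError(f"genome {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on the forward strand; wraps across the origin when
        the record is circular and ``end > length``."""
        L = self.length
        if start < 0 or start >= L:
            raise GenomeIOError(f"start {start} outside [0, {L})")
        if end <= start:
            raise GenomeIOError("end must exceed start")
        if end <= L:
            return self.sequence[start:end]
        if not self.circular:
            raise GenomeIOError("interval overruns a linear sequence")
        if end - start > L:
            raise GenomeIOError("interval span exceeds genome length")
        return self.sequence[start:] + self.sequence[: end - L]

    def fetch_interval(self, iv: "CircularInterval") -> str:
        """Strand-aware subsequence for an interval on this genome."""
        s = self.fetch(iv.start, iv.end)
        if iv.strand == "-":
            s = reverse_complement(s)
        return s


@dataclass(frozen=True)
class CircularInterval:
    """0-based half-open interval on a (possibly circular) genome.

    ``wraps`` is true when the feature crosses the origin, in which case
    ``end`` lives on the virtual doubled axis (``L < end <= 2L``).
    """

    genome_id: str
    start: int
    end: int
    strand: str = "+"
    wraps: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"bad strand {self.strand!r}")
        if self.start < 0:
            raise GenomeIOError(f"negative start {self.start}")
        if self.end <= self.start:
            raise GenomeIOError(
                f"empty interval [{self.start}, {self.end}) on {self.genome_id}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def validate(self, L: int) -> "CircularInterval":
        if self.start >= L:
            raise GenomeIOError(
                f"start {self.start} >= genome length {L} on {self.genome_id}"
            )
        limit = 2 * L if self.wraps else L
        if self.end > limit:
            raise GenomeIOError(
                f"end {self.end} beyond limit {limit} on {self.genome_id}"
            )
        if self.span > L:
            raise GenomeIOError("interval span exceeds genome length")
        if self.wraps and self.end <= L:
            raise GenomeIOError("wraps=true but interval does not cross origin")
        return self

    def overlaps(self, other: "CircularInterval", L: int | None = None) -> bool:
        """True when the two intervals share at least one position.

        ``L`` is required to resolve origin-crossing intervals.
        """
        a = self.segments(L) if L else [(self.start, self.end)]
        b = other.segments(L) if L else [(other.start, other.end)]
        return any(s1 < e0 and s0 < e1 for (s0, e0) in a for (s1, e1) in b)

    def segments(self, L: int) -> list[tuple[int, int]]:
        """Linear [start, end) pieces after cutting at the origin."""
        if self.end <= L:
            return [(self.start, self.end)]
        return [(self.start, L), (0, self.end - L)]

    def contains_point(self, pos: int, L: int) -> bool:
        return any(s <= pos < e for s, e in self.segments(L))


@dataclass(frozen=True)
class FeatureRecord:
    interval: CircularInterval
    name: str
    kind: str
    product: str | None = None

    def __post_init__(self):
        if not self.name:
            raise GenomeIOError("feature name must be non-empty")
        if self.kind not in FEATURE_KINDS:
            raise GenomeIOError(
                f"feature kind {self.kind!r} not in {FEATURE_KINDS}"
            )


# ---------------------------------------------------------------------------
# sequence I/O


def read_genome(
    path: str | Path,
    format: str = "fasta",
    circular: bool = True,
    record_id: str | None = None,
) -> GenomeRecord:
    """Read a single sequence record from a FASTA or GenBank flat file.

    A file with several records requires ``record_id`` as a selector.
    """
    if format not in ("fasta", "genbank"):
        raise GenomeIOError(f"unsupported sequence format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:  # Biopython parse errors carry position info
        raise GenomeIOError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise GenomeIOError(f"no sequence records in {path}")
    if record_id is not None:
        records = [r for r in records if r.id == record_id or r.name == record_id]
        if not records:
            raise GenomeIOError(f"record {record_id!r} not found in {path}")
    if len(records) != 1:
        raise GenomeIOError(
            f"{path} holds {len(records)} records; supply record_id to choose one"
        )
    rec = records[0]
    seq = str(rec.seq)
    if not seq:
        raise GenomeIOError(f"record {rec.id!r} in {path} has an empty sequence")
    return GenomeRecord(id=rec.id, sequence=seq, circular=circular)


def write_genome(path: str | Path, genome: GenomeRecord, format: str = "fasta") -> None:
    if format != "fasta":
        raise GenomeIOError("only FASTA output is supported")
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# feature I/O

_GFF_KIND_MAP = {
    "cds": "protein",
    "gene": "protein",
    "mrna": "protein",
    "protein": "protein",
    "rrna": "rRNA",
    "trna": "tRNA",
    "orf": "orf",
}

_GENBANK_KIND_MAP = {"CDS": "protein", "rRNA": "rRNA", "tRNA": "tRNA"}


def _canonical_interval(genome_id, start0, end0, strand, L):
    """Map raw 0-based half-open coordinates onto the canonical circular form."""
    if start0 < 0 or end0 <= start0:
        raise GenomeIOError(f"bad coordinates [{start0}, {end0}) on {genome_id}")
    if end0 > 2 * L or (end0 > L and start0 >= L):
        raise GenomeIOError(
            f"coordinates [{start0}, {end0}) out of range for length {L}"
        )
    wraps = end0 > L
    return CircularInterval(genome_id, start0, end0, strand, wraps).validate(L)


def read_features(
    path: str | Path,
    format: str,
    genome: GenomeRecord,
) -> list[FeatureRecord]:
    """Read gene annotations from GFF3, BED or a GenBank flat file.

    1-based inclusive GFF/GenBank coordinates are converted to the internal
    0-based half-open convention; features spanning the origin come back
    with ``wraps=True``.
    """
    if format == "gff3":
        return _read_gff3(path, genome)
    if format == "bed":
        return _read_bed(path, genome)
    if format == "genbank":
        return _read_genbank_features(path, genome)
    raise GenomeIOError(f"unsupported feature format {format!r}")


def _read_gff3(path, genome) -> list[FeatureRecord]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise GenomeIOError(f"cannot parse {path} as GFF3: {exc}") from exc
    feats = []
    L = genome.length
    for f in db.all_features():
        kind = _GFF_KIND_MAP.get(f.featuretype.lower())
        if kind is None:
            continue
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [f.featuretype])[0]
        product = (f.attributes.get("product") or [None])[0]
        strand = f.strand if f.strand in "+-" else "+"
        try:
            iv = _canonical_interval(genome.id, f.start - 1, f.end, strand, L)
        except GenomeIOError as exc:
            raise GenomeIOError(f"feature {name!r}: {exc}") from exc
        feats.append(FeatureRecord(iv, name, kind, product))
    return feats


def _read_bed(path, genome) -> list[FeatureRecord]:
    feats = []
    L = genome.length
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GenomeIOError(f"{path}:{lineno}: expected >=3 BED columns")
            name = cols[3] if len(cols) > 3 else f"feature_{lineno}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            try:
                iv = _canonical_interval(genome.id, int(cols[1]), int(cols[2]), strand, L)
            except GenomeIOError as exc:
                raise GenomeIOError(f"feature {name!r}: {exc}") from exc
            feats.append(FeatureRecord(iv, name, "orf"))
    return feats


def _read_genbank_features(path, genome) -> list[FeatureRecord]:
    recs = list(SeqIO.parse(str(path), "genbank"))
    if len(recs) != 1:
        raise GenomeIOError(f"{path} must hold exactly one GenBank record")
    rec = recs[0]
    L = genome.length
    feats = []
    for f in rec.features:
        kind = _GENBANK_KIND_MAP.get(f.type)
        if kind is None:
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", [f.type])[0]
        )
        product = f.qualifiers.get("product", [None])[0]
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted(
            ((int(p.start), int(p.end)) for p in f.location.parts), key=lambda p: p[0]
        )
        start0, end0 = parts[0][0], parts[-1][1]
        span = sum(e - s for s, e in parts)
        # join() across the origin: the last exon ends at L while an earlier
        # one starts at 0 -> re-express on the doubled axis.
        if len(parts) > 1 and parts[-1][1] == L and parts[0][0] == 0:
            start0 = min(s for s, e in parts if s != 0)
            end0 = L + max(e for s, e in parts if s == 0)
        try:
            iv = _canonical_interval(genome.id, start0, end0, strand, L)
        except GenomeIOError as exc:
            raise GenomeIOError(f"feature {name!r}: {exc}") from exc
        if iv.span < span:
            raise GenomeIOError(f"feature {name!r}: exon span exceeds location")
        feats.append(FeatureRecord(iv, name, kind, product))
    return feats


def write_features_bed(path: str | Path, feats: Iterable[FeatureRecord], L: int) -> None:
    """BED is 0-based half-open; wrapped features are split at the origin."""
    with open(path, "w") as fh:
        for f in feats:
            for s, e in f.interval.segments(L):
                fh.write(
                    f"{f.interval.genome_id}\t{s}\t{e}\t{f.name}\t0\t{f.interval.strand}\n"
                )


def write_features_gff3(path: str | Path, feats: Iterable[FeatureRecord], L: int) -> None:
    """GFF3 output (1-based inclusive), wrapped features split at the origin."""
    type_map = {"protein": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "orf": "ORF"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            for s, e in f.interval.segments(L):
                fh.write(
                    "\t".join(
                        [
                            f.interval.genome_id,
                            "mitoblocks",
                            type_map[f.kind],
                            str(s + 1),
                            str(e),
                            ".",
                            f.interval.strand,
                            ".",
                            f"Name={f.name}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# circular arithmetic


def circular_distance(a: int, b: int, L: int) -> int:
    """Shortest arc distance between two positions on a circle of size L."""
    if not (0 <= a < L and 0 <= b < L):
        raise GenomeIOError(f"positions ({a}, {b}) must lie in [0, {L})")
    d = abs(a - b)
    return min(d, L - d)


def rotate_origin(genome: GenomeRecord, offset: int) -> GenomeRecord:
    """Move the sequence origin by ``offset`` bp (new origin = old ``offset``)."""
    L = genome.length
    if not (0 <= offset <= L):
        raise GenomeIOError(f"offset {offset} outside [0, {L}]")
    if not genome.circular:
        raise GenomeIOError("cannot rotate a linear sequence")
    if offset in (0, L):
        return genome
    return replace(genome, sequence=genome.sequence[offset:] + genome.sequence[:offset])


def rotate_interval(iv: CircularInterval, offset: int, L: int) -> CircularInterval:
    """Interval coordinates after :func:`rotate_origin` by ``offset``."""
    start = (iv.start - offset) % L
    end = start + iv.span
    return CircularInterval(iv.genome_id, start, end, iv.strand, wraps=end > L)


_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_genome(genome: GenomeRecord) -> GenomeRecord:
    return replace(genome, sequence=reverse_complement(genome.sequence))


def revcomp_interval(iv: CircularInterval, L: int) -> CircularInterval:
    """Interval coordinates after reverse-complementing the whole genome."""
    start = (L - iv.end) % L
    end = start + iv.span
    strand = "-" if iv.strand == "+" else "+"
    return CircularInterval(iv.genome_id, start, end, strand, wraps=end > L)


# ---------------------------------------------------------------------------
# interval set algebra (circular-aware)


def _linear_segments(intervals: Sequence[CircularInterval], L: int) -> list[tuple[int, int]]:
    segs = []
    for iv in intervals:
        segs.extend(iv.segments(L))
    return sorted(segs)


def merge_intervals(intervals: Sequence[CircularInterval], L: int) -> list[tuple[int, int]]:
    """Merged linear [start, end) pieces of the union (cut at the origin)."""
    segs = _linear_segments(intervals, L)
    merged: list[list[int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(intervals: Sequence[CircularInterval], L: int) -> int:
    return sum(e - s for s, e in merge_intervals(intervals, L))


def complement_intervals(
    intervals: Sequence[CircularInterval], L: int, genome_id: str = ""
) -> list[CircularInterval]:
    """Complement of the union on the circle; origin-adjacent pieces are
    re-joined into one wrapped interval."""
    merged = merge_intervals(intervals, L)
    if not merged:
        return [CircularInterval(genome_id, 0, L)]
    gaps = []
    prev_end = merged[0][1]
    for s, e in merged[1:]:
        if s > prev_end:
            gaps.append((prev_end, s))
        prev_end = max(prev_end, e)
    head_covered = merged[0][0] == 0
    tail_covered = prev_end == L
    if not head_covered and not tail_covered:
        gaps.append((prev_end, L + merged[0][0]))  # wraps across origin
    elif not head_covered:
        gaps.append((0, merged[0][0]))
    elif not tail_covered:
        gaps.append((prev_end, L))
    out = []
    for s, e in sorted(gaps):
        out.append(CircularInterval(genome_id, s, e, wraps=e > L))
    return out


def interval_point_distance(iv: CircularInterval, pos: int, L: int) -> int:
    """Circular distance from a point to the nearest base of an interval
    (0 when the point lies inside)."""
    if iv.contains_point(pos % L, L):
        return 0
    return min(
        circular_distance(iv.start % L, pos % L, L),
        circular_distance((iv.end - 1) % L, pos % L, L),
    )


def interval_interval_distance(a: CircularInterval, b: CircularInterval, L: int) -> int:
    """Circular gap between two intervals (0 when they overlap or touch)."""
    if a.overlaps(b, L):
        return 0
    candidates = []
    for pa in (a.start % L, (a.end - 1) % L):
        candidates.append(interval_point_distance(b, pa, L))
    for pb in (b.start % L, (b.end - 1) % L):
        candidates.append(interval_point_distance(a, pb, L))
    return min(candidates)
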