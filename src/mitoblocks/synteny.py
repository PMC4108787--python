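"""Syntenic blocks, junctions and genome-unique regions.

Qualifying local alignments between two circular genomes (by default
longer than 2 kb at more than 95% identity) are grouped into labeled
syntenic blocks.  Ordering the block placements around each circle
defines junctions, classified as *overlap* (the two placements share
sequence), *abutting* (they touch exactly) or *gap* (line-specific
sequence lies between them).  The complement of the block placements is
the genome-unique sequence, the raw material of the CMS-candidate
screen.

Block identity across genomes is established by alignment linkage (two
alignments sharing essentially the same footprint on one genome belong
to the same block), never by re-searching sequence.  Duplicated
placements of a block on one genome are distinguished with prime
suffixes (6, 6', 6'').
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import (
    CircularInterval,
    GenomeRecord,
    circular_distance,
    complement_intervals,
    merge_intervals,
    union_length,
)
from .aligner import LocalAlignment

__all__ = [
    "Placement",
    "SyntenicBlock",
    "Junction",
    "UniqueRegionReport",
    "ContainmentError",
    "build_blocks",
    "order_and_junctions",
    "unique_regions",
    "aligned_fraction",
    "edge_proximity",
    "junctions_to_table",
]

PRIME = "′"


class ContainmentError(ValueError):
    """A block placement fully contains another: upstream block building
    produced inconsistent placements."""


@dataclass(frozen=True)
class Placement:
    genome_id: str
    interval: CircularInterval
    orientation: str  # "forward" | "reverse" relative to the reference placement
    label: str = ""  # block label, primed for extra copies (e.g. "6'")


@dataclass
class SyntenicBlock:
    label: str
    placements: list[Placement]
    length: int  # span of the reference placement

    def on(self, genome_id: str) -> list[Placement]:
        return [p for p in self.placements if p.genome_id == genome_id]


@dataclass(frozen=True)
class Junction:
    genome_id: str
    left_block: str
    right_block: str
    type: str  # "overlap" | "abutting" | "gap"
    overlap_len: int | None = None
    gap_interval: CircularInterval | None = None


@dataclass
class UniqueRegionReport:
    genome_id: str
    regions: list[tuple[CircularInterval, int]]
    total_unique_bp: int
    largest_regions_share: float


# ---------------------------------------------------------------------------


def _footprint_overlap(a: CircularInterval, b: CircularInterval) -> float:
    """Reciprocal overlap fraction (of the shorter interval) on one genome."""
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / min(a.span, b.span)


def build_blocks(
    alignments: list[LocalAlignment],
    min_len: int = 2000,
    min_ident: float = 95.0,
    link_overlap: float = 0.8,
) -> list[SyntenicBlock]:
    """Group threshold-passing alignments into labeled syntenic blocks.

    Two alignments are linked into one block when their footprints on
    either genome overlap by at least ``link_overlap`` of the shorter
    footprint; a block with several disjoint placements on one genome is
    a duplicated block and its extra placements get prime suffixes.
    Labels are integers assigned in descending reference-span order.
    """
    hits = [
        h
        for h in alignments
        if min(h.q.span, h.s.span) >= min_len and h.identity >= min_ident
    ]
    if not hits:
        return []
    # union-find over alignments linked by a shared footprint
    parent = list(range(len(hits)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            linked = (
                a.q.genome_id == b.q.genome_id
                and _footprint_overlap(a.q, b.q) >= link_overlap
            ) or (
                a.s.genome_id == b.s.genome_id
                and _footprint_overlap(a.s, b.s) >= link_overlap
            )
            if linked:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[LocalAlignment]] = {}
    for i, h in enumerate(hits):
        clusters.setdefault(find(i), []).append(h)

    ref_genome = hits[0].q.genome_id
    blocks = []
    for members in clusters.values():
        placements: list[Placement] = []
        for genome_attr in ("q", "s"):
            per_genome: dict[str, list[tuple[CircularInterval, str]]] = {}
            for h in members:
                iv = getattr(h, genome_attr)
                orient = (
                    "forward"
                    if (genome_attr == "q" or h.orientation == "forward")
                    else "reverse"
                )
                per_genome.setdefault(iv.genome_id, []).append((iv, orient))
            for gid, ivs in per_genome.items():
                # deduplicate near-identical footprints of linked alignments
                ivs.sort(key=lambda t: (-t[0].span, t[0].start))
                distinct: list[tuple[CircularInterval, str]] = []
                for iv, orient in ivs:
                    if all(_footprint_overlap(iv, d) < link_overlap for d, _ in distinct):
                        distinct.append((iv, orient))
                for iv, orient in distinct:
                    placements.append(Placement(gid, iv, orient))
        # self-pair (duplication detection) can list the same interval via
        # q and s; drop exact repeats
        seen = set()
        uniq = []
        for p in placements:
            key = (p.genome_id, p.interval.start, p.interval.end)
            if key not in seen:
                seen.add(key)
                uniq.append(p)
        ref_p = [p for p in uniq if p.genome_id == ref_genome]
        ref_len = max((p.interval.span for p in ref_p), default=max(p.interval.span for p in uniq))
        blocks.append(SyntenicBlock(label="", placements=uniq, length=ref_len))

    blocks.sort(key=lambda b: -b.length)
    labeled = []
    for idx, b in enumerate(blocks, 1):
        label = str(idx)
        per_genome: dict[str, list[Placement]] = {}
        for p in b.placements:
            per_genome.setdefault(p.genome_id, []).append(p)
        new_placements = []
        for gid, ps in per_genome.items():
            ps.sort(key=lambda p: (-p.interval.span, p.interval.start))
            for copy_i, p in enumerate(ps):
                new_placements.append(
                    Placement(p.genome_id, p.interval, p.orientation, label + PRIME * copy_i)
                )
        labeled.append(SyntenicBlock(label=label, placements=new_placements, length=b.length))
    return labeled


def _sorted_placements(genome: GenomeRecord, blocks: list[SyntenicBlock]) -> list[Placement]:
    ps = [p for b in blocks for p in b.on(genome.id)]
    ps.sort(key=lambda p: (p.interval.start, -p.interval.span))
    return ps


def order_and_junctions(genome: GenomeRecord, blocks: list[SyntenicBlock]) -> list[Junction]:
    """Classify the adjacency between consecutive block placements around
    the circle.  ``n`` placements yield ``n`` junctions; a single
    placement covering the whole circle yields none."""
    L = genome.length
    ps = _sorted_placements(genome, blocks)
    if not ps:
        return []
    if len(ps) == 1 and ps[0].interval.span >= L:
        return []
    # containment check: a placement strictly inside another flags an
    # upstream block-building bug
    for i, a in enumerate(ps):
        for b in ps[i + 1 :]:
            ia, ib = a.interval, b.interval
            if (ia.start <= ib.start and ia.end >= ib.end and ia.span > ib.span) or (
                ib.start <= ia.start and ib.end >= ia.end and ib.span > ia.span
            ):
                raise ContainmentError(
                    f"placement {b.label or b.genome_id} contained in {a.label} on {genome.id}"
                )
    junctions = []
    n = len(ps)
    for i in range(n):
        left = ps[i]
        right = ps[(i + 1) % n]
        left_end = left.interval.end
        right_start = right.interval.start + (L if i == n - 1 else 0)
        if left_end > right_start:
            junctions.append(
                Junction(genome.id, left.label, right.label, "overlap",
                         overlap_len=left_end - right_start)
            )
        elif left_end == right_start:
            junctions.append(Junction(genome.id, left.label, right.label, "abutting"))
        else:
            gap = CircularInterval(genome.id, left_end % L,
                                   (left_end % L) + (right_start - left_end),
                                   wraps=(left_end % L) + (right_start - left_end) > L)
            junctions.append(
                Junction(genome.id, left.label, right.label, "gap", gap_interval=gap)
            )
    return junctions


def unique_regions(
    genome: GenomeRecord, blocks: list[SyntenicBlock], top_n: int = 2
) -> UniqueRegionReport:
    """Genome-specific sequence: the complement of the union of this
    genome's block placements.  ``largest_regions_share`` is the combined
    share of the ``top_n`` largest regions (the study sums the two
    largest line-specific segments)."""
    L = genome.length
    ivs = [p.interval for b in blocks for p in b.on(genome.id)]
    regions = complement_intervals(ivs, L, genome.id)
    if union_length(ivs, L) >= L:
        regions = []
    pairs = sorted(((r, r.span) for r in regions), key=lambda t: -t[1])
    total = sum(sp for _, sp in pairs)
    share = 100.0 * sum(sp for _, sp in pairs[:top_n]) / total if total else 0.0
    return UniqueRegionReport(genome.id, pairs, total, share)


def aligned_fraction(
    genome: GenomeRecord, alignments: list[LocalAlignment], side: str = "query"
) -> float:
    """Percent of this genome covered by the union of its aligned
    positions (each position counted once)."""
    if side not in ("query", "subject"):
        raise ValueError("side must be 'query' or 'subject'")
    attr = "q" if side == "query" else "s"
    ivs = [getattr(h, attr) for h in alignments if getattr(h, attr).genome_id == genome.id]
    return 100.0 * union_length(ivs, genome.length) / genome.length


def edge_proximity(
    blocks_xy: list[SyntenicBlock],
    blocks_xz: list[SyntenicBlock],
    genome: GenomeRecord,
    max_dist: int = 2000,
) -> list[tuple[tuple[str, int], tuple[str, int], int]]:
    """Block-end regions of one block set lying near edges of another.

    For every placement edge of ``blocks_xy`` on ``genome``, report the
    nearest placement edge of ``blocks_xz`` when the circular distance is
    at most ``max_dist``; each ``blocks_xy`` edge is reported once.
    Edges are (label, position) pairs.
    """
    L = genome.length

    def edges(blocks):
        out = []
        for b in blocks:
            for p in b.on(genome.id):
                out.append((p.label or b.label, p.interval.start % L))
                out.append((p.label or b.label, (p.interval.end - 1) % L))
        return out

    e1, e2 = edges(blocks_xy), edges(blocks_xz)
    results = []
    for lab1, pos1 in e1:
        best = None
        for lab2, pos2 in e2:
            d = circular_distance(pos1, pos2, L)
            if best is None or d < best[2]:
                best = ((lab1, pos1), (lab2, pos2), d)
        if best is not None and best[2] <= max_dist:
            results.append(best)
    return results


def junctions_to_table(junctions: list[Junction]) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for j in junctions:
        rows.append(
            {
                "genome": j.genome_id,
                "left": j.left_block,
                "right": j.right_block,
                "type": j.type,
                "bp": j.overlap_len
                if j.type == "overlap"
                else (j.gap_interval.span if j.type == "gap" else 0),
            }
        )
    return pd.DataFrame(rows, columns=["genome", "left", "right", "type", "bp"])
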