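"""Genome-level summary statistics: size, GC, coding / plastid-derived /
repeated sequence accounting and gene counts.

Plastid-derived sequence is screened by aligning the mitogenome against
the plastid genome at deliberately loose thresholds (50 bp, 80%); the
published figures for this quantity are known to be methodology-
sensitive, so the thresholds are exposed in the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aligner import AlignParams, local_align
from .genome_io import (
    CircularInterval,
    FeatureRecord,
    GenomeRecord,
    merge_intervals,
    union_length,
)
from .repeats import RepeatCoverage

__all__ = ["GenomeSummary", "plastid_screen", "summarize", "summary_table"]

RELAXED_SCREEN = AlignParams(k=11, min_len=50, min_ident=80.0)


@dataclass
class GenomeSummary:
    genome_id: str
    size: int
    gc: float
    coding_bp: int
    coding_pct: float
    plastid_bp: int
    plastid_pct: float
    repeat_bp: int
    repeat_pct: float
    n_genes: int
    n_protein_genes: int
    n_rrna: int
    n_trna: int
    n_trna_plastid: int


def plastid_screen(
    mito: GenomeRecord,
    plastid: GenomeRecord,
    params: AlignParams | None = None,
) -> tuple[list[CircularInterval], int]:
    """Mitogenome positions covered by qualifying plastid alignments.

    Returns the merged intervals on the mitogenome and their union size.
    """
    params = params or RELAXED_SCREEN
    hits = local_align(mito, plastid, params)
    ivs = [h.q for h in hits]
    merged = [
        CircularInterval(mito.id, s, e, wraps=e > mito.length)
        for s, e in merge_intervals(ivs, mito.length)
    ]
    return merged, union_length(ivs, mito.length)


def summarize(
    genome: GenomeRecord,
    features: list[FeatureRecord],
    repeat_cov: RepeatCoverage | None = None,
    plastid_bp: int = 0,
    plastid_intervals: list[CircularInterval] | None = None,
) -> GenomeSummary:
    """Table-style genome summary.

    GC counts G and C only (ambiguity codes stay in the denominator);
    coding bp is the union of all protein and rRNA gene intervals, every
    copy of a duplicated gene included (copies at distinct loci
    contribute their full span; overlapping footprints are counted
    once).  tRNA genes lying inside plastid-derived intervals are
    sub-counted when those intervals are supplied.
    """
    L = genome.length
    seq = genome.sequence
    gc = 100.0 * (seq.count("G") + seq.count("C")) / L
    coding_ivs = [f.interval for f in features if f.kind in ("protein", "rRNA")]
    coding_bp = union_length(coding_ivs, L)
    trnas = [f for f in features if f.kind == "tRNA"]
    n_trna_plastid = 0
    if plastid_intervals:
        for t in trnas:
            if any(t.interval.overlaps(p, L) for p in plastid_intervals):
                n_trna_plastid += 1
    n_protein = sum(1 for f in features if f.kind == "protein")
    n_rrna = sum(1 for f in features if f.kind == "rRNA")
    repeat_bp = repeat_cov.covered_bp if repeat_cov else 0
    return GenomeSummary(
        genome_id=genome.id,
        size=L,
        gc=gc,
        coding_bp=coding_bp,
        coding_pct=100.0 * coding_bp / L,
        plastid_bp=plastid_bp,
        plastid_pct=100.0 * plastid_bp / L,
        repeat_bp=repeat_bp,
        repeat_pct=100.0 * repeat_bp / L,
        n_genes=n_protein + n_rrna + len(trnas),
        n_protein_genes=n_protein,
        n_rrna=n_rrna,
        n_trna=len(trnas),
        n_trna_plastid=n_trna_plastid,
    )


def summary_table(summaries: list[GenomeSummary]) -> "pandas.DataFrame":
    """Formatted multi-genome feature table (percentages to 1 decimal)."""
    import pandas as pd

    rows = {
        "Genome size (bp)": [s.size for s in summaries],
        "GC content (%)": [round(s.gc, 1) for s in summaries],
        "Coding sequences (bp)": [
            f"{s.coding_bp} ({s.coding_pct:.1f}%)" for s in summaries
        ],
        "Plastid-derived sequences (bp)": [
            f"{s.plastid_bp} ({s.plastid_pct:.1f}%)" for s in summaries
        ],
        "Repeated sequences (bp)": [
            f"{s.repeat_bp} ({s.repeat_pct:.1f}%)" for s in summaries
        ],
        "Gene content (number)": [s.n_genes for s in summaries],
        "Protein coding genes": [s.n_protein_genes for s in summaries],
        "rRNAs": [s.n_rrna for s in summaries],
        "tRNAs": [f"{s.n_trna} ({s.n_trna_plastid})" for s in summaries],
    }
    return pd.DataFrame(rows, index=[s.genome_id for s in summaries]).T
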