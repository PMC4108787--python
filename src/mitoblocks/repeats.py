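"""Within-genome repeated sequences and non-redundant repeat coverage.

A repeat is a pair of genome intervals at least ``min_len`` bp long whose
copies align at ``min_ident`` percent identity or better (defaults 100 bp
and 95%, the conventional thresholds for intermediate-sized plant
mitochondrial repeats).  Coverage counts every nucleotide included in at
least one repeat copy exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aligner import AlignParams, self_align
from .genome_io import CircularInterval, GenomeRecord, union_length

__all__ = ["RepeatMatch", "RepeatCoverage", "detect_repeats", "repeat_coverage",
           "repeats_to_table"]


@dataclass(frozen=True)
class RepeatMatch:
    a: CircularInterval
    b: CircularInterval
    identity: float
    span: int
    orientation: str  # "direct" | "inverted"


@dataclass(frozen=True)
class RepeatCoverage:
    genome_id: str
    covered_bp: int
    fraction: float  # percent of the genome
    n_matches: int
    largest_span: int


def detect_repeats(
    genome: GenomeRecord,
    min_len: int = 100,
    min_ident: float = 95.0,
    params: AlignParams | None = None,
) -> list[RepeatMatch]:
    """Self-alignment of the genome, reported as canonical repeat pairs.

    Forward self-hits become *direct* repeats, reverse hits *inverted*
    ones; each pair is reported once with ``a.start < b.start``.
    """
    if params is None:
        params = AlignParams(min_len=min_len, min_ident=min_ident)
    else:
        params = AlignParams(**{**params.__dict__, "min_len": min_len, "min_ident": min_ident})
    hits = self_align(genome, params)
    out = []
    for h in hits:
        out.append(
            RepeatMatch(
                a=h.q,
                b=h.s,
                identity=h.identity,
                span=min(h.q.span, h.s.span),
                orientation="direct" if h.orientation == "forward" else "inverted",
            )
        )
    out.sort(key=lambda r: (r.a.start, r.b.start))
    return out


def repeat_coverage(matches: list[RepeatMatch], L: int, genome_id: str = "") -> RepeatCoverage:
    """Union of all repeat copies (both members of every pair), circular-
    aware, counted without repetition."""
    ivs = [r.a for r in matches] + [r.b for r in matches]
    covered = union_length(ivs, L)
    if not genome_id and matches:
        genome_id = matches[0].a.genome_id
    return RepeatCoverage(
        genome_id=genome_id,
        covered_bp=covered,
        fraction=100.0 * covered / L,
        n_matches=len(matches),
        largest_span=max((r.span for r in matches), default=0),
    )


def repeats_to_table(matches: list[RepeatMatch]) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for r in matches:
        rows.append(
            {
                "genome": r.a.genome_id,
                "a_start": r.a.start + 1,
                "a_end": r.a.end,
                "b_start": r.b.start + 1,
                "b_end": r.b.end,
                "span": r.span,
                "identity": round(r.identity, 1),
                "orientation": r.orientation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["genome", "a_start", "a_end", "b_start", "b_end", "span",
                 "identity", "orientation"],
    )
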