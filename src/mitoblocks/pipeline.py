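"""End-to-end orchestration of the comparative mitogenome analysis.

``run_analysis`` composes the whole chain in memory:

    align -> syntenic blocks -> junctions -> unique regions -> repeats
    -> (plastid screen) -> ORF scan -> comparative classification
    -> candidate screen -> genome summaries

``run_pipeline`` is the file-based wrapper: it reads FASTA/GenBank
genomes plus optional annotations, runs the analysis and writes the
TSV/BED/GFF3/FASTA/SVG output bundle.  Given the same inputs and
configuration the outputs are byte-identical (floats are rounded at
write time).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .aligner import AlignParams, LocalAlignment, alignments_to_table, local_align
from .genome_io import (
    FeatureRecord,
    GenomeRecord,
    read_features,
    read_genome,
    write_features_bed,
)
from .genomestats import GenomeSummary, plastid_screen, summarize, summary_table
from .orfscan import (
    CandidateReport,
    OrfRecord,
    classify_orfs,
    find_orfs,
    predict_tm,
    screen_candidates,
)
from .repeats import RepeatCoverage, detect_repeats, repeat_coverage, repeats_to_table
from .synteny import (
    Junction,
    SyntenicBlock,
    UniqueRegionReport,
    aligned_fraction,
    build_blocks,
    junctions_to_table,
    order_and_junctions,
    unique_regions,
)

logger = logging.getLogger("mitoblocks")

__all__ = ["PipelineConfig", "PipelineResult", "run_analysis", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, one tier per comparison.

    Defaults are the conventional ones for plant mitogenome comparisons:
    syntenic blocks at 2 kb / 95%, repeats at 100 bp / 95%, a relaxed
    tier (50 bp / 80%) for whole-genome aligned fractions and the
    plastid screen, 2 kb proximity for the candidate screen, ORFs above
    100 amino acids, Kyte-Doolittle window 19 at mean 1.6.
    """

    genome_a: str | Path | None = None
    genome_b: str | Path | None = None
    features_a: str | Path | None = None
    features_b: str | Path | None = None
    feature_format: str = "gff3"
    plastid: str | Path | None = None
    outdir: str | Path = "mitoblocks_out"
    seed: int = 0

    block_min_len: int = 2000
    block_min_ident: float = 95.0
    repeat_min_len: int = 100
    repeat_min_ident: float = 95.0
    align_params: AlignParams = field(
        default_factory=lambda: AlignParams(min_len=500, min_ident=90.0)
    )
    relaxed_params: AlignParams = field(
        default_factory=lambda: AlignParams(k=11, min_len=50, min_ident=80.0)
    )
    max_dist: int = 2000
    orf_min_aa: int = 100
    tm_window: int = 19
    tm_threshold: float = 1.6


@dataclass
class PipelineResult:
    genomes: dict[str, GenomeRecord]
    alignments: list[LocalAlignment]
    relaxed_alignments: list[LocalAlignment]
    blocks: list[SyntenicBlock]
    junctions: dict[str, list[Junction]]
    unique: dict[str, UniqueRegionReport]
    aligned_pct: dict[str, float]
    repeats: dict[str, list]
    repeat_cov: dict[str, RepeatCoverage]
    plastid_intervals: dict[str, list]
    plastid_bp: dict[str, int]
    orfs: dict[str, list[OrfRecord]]
    candidates: dict[str, CandidateReport]
    summaries: dict[str, GenomeSummary]


def run_analysis(
    A: GenomeRecord,
    B: GenomeRecord,
    features_a: list[FeatureRecord] | None = None,
    features_b: list[FeatureRecord] | None = None,
    plastid: GenomeRecord | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full comparative analysis on in-memory genomes."""
    cfg = config or PipelineConfig()
    features = {A.id: features_a or [], B.id: features_b or []}
    t0 = time.time()

    logger.info("aligning %s vs %s", A.id, B.id)
    hits = local_align(A, B, cfg.align_params)
    relaxed = local_align(A, B, cfg.relaxed_params)
    blocks = build_blocks(hits, cfg.block_min_len, cfg.block_min_ident)
    junctions = {g.id: order_and_junctions(g, blocks) for g in (A, B)}
    unique = {g.id: unique_regions(g, blocks) for g in (A, B)}
    aligned_pct = {
        A.id: aligned_fraction(A, relaxed, "query"),
        B.id: aligned_fraction(B, relaxed, "subject"),
    }

    logger.info("detecting repeats")
    reps = {
        g.id: detect_repeats(g, cfg.repeat_min_len, cfg.repeat_min_ident)
        for g in (A, B)
    }
    rep_cov = {g.id: repeat_coverage(reps[g.id], g.length, g.id) for g in (A, B)}

    plastid_iv = {A.id: [], B.id: []}
    plastid_bp = {A.id: 0, B.id: 0}
    if plastid is not None:
        logger.info("plastid screen")
        for g in (A, B):
            ivs, bp = plastid_screen(g, plastid, cfg.relaxed_params)
            plastid_iv[g.id], plastid_bp[g.id] = ivs, bp

    logger.info("scanning ORFs")
    orfs = {}
    candidates = {}
    for focal, other in ((A, B), (B, A)):
        found = find_orfs(focal, cfg.orf_min_aa, features[focal.id])
        classify_orfs(found, focal, other)
        for o in found:
            o.tm, o.tm_segments = predict_tm(o.protein, cfg.tm_window, cfg.tm_threshold)
        orfs[focal.id] = found
        novel = [o for o in found if not o.overlaps_known_gene]
        candidates[focal.id] = screen_candidates(
            novel, blocks, reps[focal.id], focal, cfg.max_dist
        )

    summaries = {
        g.id: summarize(
            g,
            features[g.id],
            rep_cov[g.id],
            plastid_bp[g.id],
            plastid_iv[g.id],
        )
        for g in (A, B)
    }
    logger.info("analysis finished in %.1f s", time.time() - t0)
    return PipelineResult(
        genomes={A.id: A, B.id: B},
        alignments=hits,
        relaxed_alignments=relaxed,
        blocks=blocks,
        junctions=junctions,
        unique=unique,
        aligned_pct=aligned_pct,
        repeats=reps,
        repeat_cov=rep_cov,
        plastid_intervals=plastid_iv,
        plastid_bp=plastid_bp,
        orfs=orfs,
        candidates=candidates,
        summaries=summaries,
    )


def _orf_table(orfs: list[OrfRecord]):
    import pandas as pd

    rows = []
    for o in orfs:
        rows.append(
            {
                "name": o.name,
                "start": o.interval.start + 1,
                "end": o.interval.end,
                "strand": o.strand,
                "aa_len": o.aa_len,
                "class": o.orf_class or "",
                "known_gene_overlap": o.overlaps_known_gene,
                "tm": o.tm,
                "dist_block_edge": "" if o.dist_block_edge is None else o.dist_block_edge,
                "dist_repeat": "" if o.dist_repeat is None else o.dist_repeat,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "start", "end", "strand", "aa_len", "class",
                 "known_gene_overlap", "tm", "dist_block_edge", "dist_repeat"],
    )


def _candidate_table(report: CandidateReport):
    import pandas as pd

    rows = []
    for r in report.rows:
        rows.append(
            {
                "name": r.orf.name,
                "class": r.orf.orf_class or "",
                "chimeric_or_unique": r.is_chimeric_or_unique,
                "near_block_edge": r.near_block_edge,
                "near_repeat": r.near_repeat,
                "tm": r.has_tm,
                "candidate": r.is_candidate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "class", "chimeric_or_unique", "near_block_edge",
                 "near_repeat", "tm", "candidate"],
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write the TSV/BED/FASTA/SVG bundle of one analysis run."""
    from .blockmap import render_block_map

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    alignments_to_table(result.alignments).to_csv(out / "alignments.tsv", sep="\t", index=False)
    junc_all = [j for js in result.junctions.values() for j in js]
    junctions_to_table(junc_all).to_csv(out / "junctions.tsv", sep="\t", index=False)
    for gid, genome in result.genomes.items():
        L = genome.length
        with open(out / f"blocks_{gid}.bed", "w") as fh:
            for b in result.blocks:
                for p in b.on(gid):
                    for s, e in p.interval.segments(L):
                        strand = "+" if p.orientation == "forward" else "-"
                        fh.write(f"{gid}\t{s}\t{e}\tblock_{p.label}\t0\t{strand}\n")
        with open(out / f"unique_{gid}.bed", "w") as fh:
            for iv, span in result.unique[gid].regions:
                for s, e in iv.segments(L):
                    fh.write(f"{gid}\t{s}\t{e}\tunique\t{span}\t+\n")
        repeats_to_table(result.repeats[gid]).to_csv(
            out / f"repeats_{gid}.tsv", sep="\t", index=False
        )
        _orf_table(result.orfs[gid]).to_csv(out / f"orfs_{gid}.tsv", sep="\t", index=False)
        _candidate_table(result.candidates[gid]).to_csv(
            out / f"candidates_{gid}.tsv", sep="\t", index=False
        )
        with open(out / f"proteins_{gid}.faa", "w") as fh:
            for o in result.orfs[gid]:
                fh.write(f">{o.name}\n{o.protein}\n")
    summary_table(list(result.summaries.values())).to_csv(out / "summary.tsv", sep="\t")
    render_block_map(
        list(result.genomes.values()),
        result.blocks,
        result.repeats,
        {gid: rep.final_candidates for gid, rep in result.candidates.items()},
        {gid: {o.name: o.interval for o in result.orfs[gid]} for gid in result.genomes},
        out / "blockmap.svg",
    )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs, analyse, write the bundle."""
    if config.genome_a is None or config.genome_b is None:
        raise ValueError("genome_a and genome_b paths are required")

    def _load(path):
        fmt = "genbank" if str(path).endswith((".gb", ".gbk", ".genbank")) else "fasta"
        return read_genome(path, fmt)

    A = _load(config.genome_a)
    B = _load(config.genome_b)
    feats_a = (
        read_features(config.features_a, config.feature_format, A)
        if config.features_a
        else []
    )
    feats_b = (
        read_features(config.features_b, config.feature_format, B)
        if config.features_b
        else []
    )
    plastid = _load(config.plastid) if config.plastid else None
    result = run_analysis(A, B, feats_a, feats_b, plastid, config)
    write_outputs(result, config.outdir)
    return result
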