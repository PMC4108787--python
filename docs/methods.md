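# Methods

## The analysis model

Plant mitochondrial genomes are modeled as single circular molecules
("master circles") with an arbitrary origin. All coordinates are 0-based
half-open internally; a feature crossing the origin is stored canonically
with `start < L` and `end ≤ 2L` on a virtual doubled axis. Reports emit
1-based inclusive coordinates (BED stays 0-based half-open). Every
genome-level statistic is required to be invariant under rotation of the
origin and under reverse-complementing a genome — this is asserted by
tests, and is the reason for the canonical-interval discipline.

The comparison of two lines proceeds in tiers, each with its own
thresholds (all exposed in `PipelineConfig`):

| tier | definition | default |
|---|---|---|
| syntenic blocks | aligned span ≥ `block_min_len`, identity ≥ `block_min_ident` | 2 000 bp, 95% |
| repeats | self-alignment copies ≥ `repeat_min_len`, ≥ `repeat_min_ident` | 100 bp, 95% |
| relaxed tier (aligned fraction, plastid screen) | ≥ 50 bp, ≥ 80% | k = 11 seeds |
| proximity | circular distance to block edge / repeat | < 2 000 bp |
| ORFs | ATG→stop, strictly > `orf_min_aa` residues | 100 aa |
| transmembrane | Kyte–Doolittle window mean ≥ threshold | window 19, 1.6 |

These are the conventional values for intermediate-repeat and synteny
analysis of plant mitogenomes; the 2 kb/95%, 100 bp/95%, <2 kb and >100 aa
values are the thresholds the candidate screen is defined by.

## Alignment engine

`local_align` is a seed–chain–extend heuristic. 2-bit-packed exact k-mers
(default k = 12; k = 11 in the relaxed tier) are matched through a sorted
index; matches are clustered along diagonals (gap ≤ 100 bp, diagonal drift
≤ 75 bp); each cluster window is aligned and trimmed to its best local
segment under the affine score (match +1, mismatch −2, gap open −3, gap
extend −2; a gap of length g costs `open + g·extend`). Window alignment is
edlib in infix mode followed by a Kadane scan over the alignment columns;
windows up to 400 bp a side that pass a cheap screen are re-aligned with an
exact vectorized Gotoh DP (own implementation, with traceback), because the
unit-cost edit path can place gaps differently from the affine optimum.
Identity is matched columns / all alignment columns — gap columns count
against identity — and ambiguity codes never count as matches (nor as G/C
in GC content).

Circularity is handled by doubling each circular axis, searching plainly,
and keeping canonical hits (both starts < L); duplicate discoveries
(including the mirror image of an inverted repeat and re-discoveries across
the origin) are collapsed when ≥90% of both footprints coincide modulo L.
Both orientations are searched by reverse-complementing the subject.
Sensitivity note: a qualifying hit needs at least one exact k-mer, so the
relaxed tier (80% identity) is not guaranteed to find short diverged
segments with no 11-mer anchor; planted-truth tests use exact or
high-identity segments where this cannot bite.

`dp_oracle_align` is the exact best local alignment under the same scores,
computed by Biopython's `PairwiseAligner` — an independent code path used
as the test oracle (inputs capped at 5 kb; among co-optimal alignments the
library's first is returned, which is deterministic). The acceptance suite
drives 200 random homologous pairs (≤300 bp) through both routes and
requires the heuristic to reach ≥95% of the oracle score; in practice the
agreement is exact because qualifying small windows take the exact-DP
refinement path.

## Blocks, junctions, unique regions

Alignments passing the block thresholds are linked into blocks when their
footprints on either genome overlap by ≥80% of the shorter footprint
(union–find); a block with several disjoint placements on one genome is a
duplicated block, and extra placements get prime suffixes (6, 6′). Labels
are integers in descending reference-span order. Junctions are classified
by walking placements around each circle: `overlap` when consecutive
placements share sequence, `abutting` when they touch exactly, `gap`
otherwise (the intervening interval is attached). n placements yield n
junctions; one full-circle placement yields none; a placement strictly
containing another raises an error, since block building should never
produce that. Unique regions are the circular complement of the block
placements; `largest_regions_share` sums the two largest regions by
default (configurable), mirroring the convention of summing the two named
largest line-specific segments. Block union plus unique bp equals L exactly
on every genome — a conservation law the tests assert.

The cross-relationship that motivates the junction taxonomy — an overlap
junction in one genome corresponds to a repeated sequence at block edges in
the other — is exercised on synthetic data where it is true by
construction.

## ORF classification and candidate screen

ORFs are scanned in all six frames of the doubled circular sequence
(standard genetic code, table 1; per frame and stop codon only the longest
ATG-initiated reading; strictly >100 aa; named `orf<aa>`, with letter
suffixes on length collisions). ORFs overlapping annotated protein/rRNA
genes are flagged and excluded from novel-ORF counts but not discarded.

Classification aligns an ORF's nucleotide sequence to the counterpart
genome at the relaxed tier and combines query coverage with the number of
source loci (hit clusters separated by >2 kb or in opposite orientations):
identical (single locus, ≥99% coverage, all hits at 100% identity),
polymorphic (single locus, ≥90%), chimeric (≥2 loci jointly ≥40%, or a
single locus at 40–90% with the remainder unmatched), unique (<40%). The
coverage cut-offs are package-defined defaults — the defining worked case
is a chimeric ORF whose 5′ part matches a repeat found elsewhere while the
3′ part matches nothing — and they are all configurable.

Transmembrane prediction is Kyte–Doolittle hydropathy averaged over a
19-residue window; a TM segment is a maximal run of window centers with
mean ≥1.6. This is a deliberately transparent stand-in for dedicated
HMM-based predictors: adequate for the screen's yes/no flag on strongly
hydrophobic cores, not a topology predictor.

The final screen takes the conjunction of four flags per ORF — chimeric or
unique, within 2 kb of a block-placement edge, within 2 kb of a repeat
copy (distance 0 when overlapping), and TM-positive. Known genes can be
injected into the same screen even though they are not novel ORFs (the
truncated-atp6 use case).

## Annotated gene comparison

Gene pairs matched by name are compared in coding orientation. Terminal
rearrangements are detected from the best local alignment: if it stops
≥30 bp short of a gene end, a `rearranged_5prime`/`rearranged_3prime` call
is emitted with the boundary position. Variant calls come from a full-gene
global alignment (affine, indels left-normalized to their leftmost
equivalent placement) with a 45 bp exclusion margin around rearrangement
breakpoints: substitution runs become SNP calls with the codon context of
both alleles (site = 1-based start of the first affected codon) and a
synonymy call; indels with length ≡ 0 (mod 3) become in-frame indel calls
with the affected codons translated. A non-synonymous substitution whose
amino-acid difference vanishes when every polymorphic C is read as U is
flagged `editing_sensitive` (the plant-mitochondrial C-to-U editing
caveat). An outgroup sequence, when given, is locally aligned to the first
gene and each polymorphic site is polarized (`matches_first` /
`matches_second` / `unknown`, the latter also covering sites the outgroup
does not span).

## Synthetic data: what it emulates and what it does not

`generate_pair` builds two circular genomes from one pool of shared blocks
(default: ~150 kb, 8 blocks of 8–25 kb scaled to the target size), applies
transpositions and inversions to the second genome's order, separates
blocks with line-specific filler (four inserts of 12/6/3/2 kb alternating
between lines plus 300–800 bp spacers at every remaining junction), and
plants three structural signals:

* **Edge repeats / overlap junctions.** For each planted repeat, genome A
  carries the segment at the facing edges of two blocks (a repeat pair)
  while genome B places those blocks adjacently sharing a single copy, so
  B's placements overlap. This reproduces the real correspondence between
  overlap junctions and counterpart edge repeats, by construction.
* **Plastid segments.** A 30 kb synthetic plastid genome donates 1 kb
  segments into line-specific inserts.
* **A candidate ORF.** One 152-aa ORF at the start of A's largest insert:
  5′ third copied in-frame from the first edge repeat (hence chimeric, and
  overlapping a repeat copy), a 30-codon Leu/Ile/Val core (hence TM), a
  novel 3′ end, within ~120 bp of a block edge.

SNPs (default 0.5%) hit only shared blocks, never planted repeats, so
repeat identities stay controlled. Background ORFs that would tie the
candidate on all four criteria are neutralized at generation time by
writing an in-frame stop codon into line-specific filler (never into
blocks, repeats, plastid segments or the candidate); if no patchable codon
exists, generation retries with a derived sub-seed — the output remains a
deterministic function of the seed, and identical seeds give identical
bytes.

Because every non-overlap junction carries a spacer, default truth contains
no abutting junctions: exact abutment is measure-zero in real data, and a
single chance-matching base at an abutting boundary would flip the detected
type. Abutting classification is covered by direct unit tests and by the
degenerate `spacer_len_range=(0,0)` configuration (which with no
rearrangements, inserts or SNPs yields byte-identical genomes).

Limitations of the generator, hence of what passing tests show: background
sequence is i.i.d. uniform (real mitogenomes are ~45% GC with skewed
composition and microhomology); mutations are SNP-only within blocks (no
indel spectrum, no recombination process over generations); repeats are
planted at 100% identity by default; substoichiometric molecules are not
modeled. Recovery being exact under these conditions demonstrates the
pipeline's bookkeeping (coordinates, circularity, thresholds, screening
logic), not alignment sensitivity on diverged real data.

## Problem sizes and numerical choices

The default synthetic conditions (~150 kb per genome) run the full
pipeline in well under a minute on one CPU; the test suite uses a ~45 kb
4-block pair for most end-to-end checks and the full default pair for the
recovery and conservation tests. Boundary recovery is scored as the mean
absolute circular error over all placement starts/ends (observed ≤1 bp;
the tests allow 20 bp, the slack covering chance single-base extensions at
junction boundaries). Ties in placement ordering break by start then
longer-span-first; hit deduplication prefers longer alignments. Percentages
are reported to one decimal. Degenerate inputs: empty alignment lists give
empty block lists (not errors); a genome aligned to itself reports a single
full-length placement and zero unique bp; proteins shorter than the TM
window are never TM-positive.
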