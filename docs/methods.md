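# Methods

This note records the model behind `refusion`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Evidence model

The caller assumes coordinate-sorted alignments from a split-aware spliced
mapper of an FR paired-end library. Three alignment signatures carry fusion
information:

- **chimeric reads** — one read aligned in two segments to different
  chromosomes/strands or across more than the maximum intron length
  (`max_intron`, default 200 kb);
- **partial reads** — one end clipped, the clipped sequence belonging to the
  partner locus;
- **discordant pairs** — mates on different chromosomes, in the same strand
  orientation, or farther apart than `max_intron`.

A pair is *discordant* exactly under those three conditions; a chimeric
read, split and viewed as a pair, is discordant by construction. Breakpoint
calls carry a tier (1–4) equal to the strongest criterion satisfied, and a
read satisfying criterion 1 is never reported at a weaker tier.

"Consistent with X" — used when counting supporting neighbours — means: a
discordant alignment whose span comes within `neighbor_window` (200 bp) of
X's anchor and whose mate implies the same (chromosome, strand) for the
partner side. The window reuses the only distance printed for the scan.
Criterion 3 is applied to any partial read that fails criterion 2 — whether
because its clip is short, contains Ns, or has too few t₁-neighbours — so
that lowering a threshold can only add calls (monotonicity).

The minimum unmapped part for criterion 2 is `clamp(l/5, kmer, 1.5*kmer)`
with `kmer` the mapper's genome seed size (≤ 16, default 15): for 100 nt
reads this is 20 nt.

Criterion 4 groups entirely aligned discordant pairs by the ordered
(chromosome, strand, mate chromosome, mate strand) signature — mixed groups
are split by partner — clusters them by single linkage within the
neighbour window, and emits one call per fusion *side* at the farthest 3'
extension of that side's reads; a fully covered fusion therefore yields a
call (and a candidate region) on each partner locus, which downstream
deduplication merges.

## Candidate regions and assembly

Grouped calls (single linkage, ≤ 200 bp, repeat-region calls removed first;
representative = lowest tier, then most support, then smallest position)
define ±250 bp regions, clipped at chromosome ends and never merged.

Abnormal pairs anchored in a region are assembled with a single-k de Bruijn
assembler on canonical k-mers:

| parameter | default | rationale |
|---|---|---|
| k | 21 | odd (no palindromic k-mers), short enough for 100 nt reads, long enough to be unique in a Mb-scale toy genome |
| min_kmer_cov | 2 | removes singleton error k-mers at ≥ 15× regional coverage |
| tip_len | 2k | standard short-dead-end clipping |

Bubbles (parallel unitigs sharing both flanking nodes) are popped by mean
coverage, ties broken lexicographically. Contigs are maximal unbranched
paths ≥ k, reported in canonical orientation (lexicographic minimum of
sequence and reverse complement) and ordered by read support then sequence,
so assembly output is deterministic. Multi-k merging and isoform resolution
of a full transcriptome assembler are deliberately out of scope: the target
is one junction-spanning contig per region. An external contig FASTA can be
substituted via `pipeline.detect(contigs_from=...)`.

## Contig re-alignment, chaining, junctions

Re-alignment is exact-seed (default 15 nt, 2-bit-encoded sorted-array
index) and ungapped extension on both strands. Two scoring rules coexist on
purpose:

- **boundary placement** during extension maximises a running score of
  match +1 / mismatch −2 and stops after 3 consecutive mismatches, then
  trims each segment end until its terminal 6 bases match exactly. Random
  continuation past a true junction matches ~1/4 of bases, so a spurious
  extension would need better than a 2:1 match ratio ending in a 6-mer
  exact run — this keeps segment ends pinned to the junction;
- **reported segment score** is plain matches − mismatches (match +1,
  mismatch −1), the quantity aggregated by chaining.

Segments whose contig interval (≥ 90% mutual overlap) maps to more than one
genomic locus with the runner-up within 95% of the best score are removed
as non-unique, approximating BLAT's near-best filtering.

Chaining is an exact two-best dynamic programme over segments ordered by
contig start; consecutive members may overlap by ≤ 15 nt in contig
coordinates (microhomology tolerance) with free genomic jumps. A segment's
contribution is reduced by its contig overlap with the predecessor, so the
aggregate q₁ never exceeds the contig length q₀ and Q stays in [0, 1]. The
second-best chain is the best-scoring chain with a different segment set;
when none exists the second exponential term of Q is zero.

A junction is called when two consecutive best-path segments belong to
different genes with overlap ≤ 15 nt. Within an overlap the exact split is
ambiguous; when genome sequence is available the split maximising total
matched bases is chosen (ties at the smallest split). The 5' partner is the
gene upstream in the fused transcript: if the left-on-contig segment aligns
on its gene's strand the contig reads in transcript sense, otherwise the
contig is the reverse complement of the fused transcript and the partners
swap. Genes are assigned per segment by largest covered span; low-Q contigs
(Q < 0.5) and breakpoints inside repeat/self-chain intervals are flagged,
not dropped, at this stage.

## Support, scores, filters

Reads of the region's abnormal pairs (plus initially unmapped mates) are
re-aligned to the junction contig ungapped in both orientations (13-mer
seeding, ≥ 90% identity). A read spans the junction if its placement covers
the contig break with ≥ 13 nt on each side (L, R = aligned bases per side,
clipped bases do not count); otherwise a pair whose mates place on opposite
sides encompasses it. Redundancy is collapsed on the (read offset, mate
offset) pair, so PCR duplicates count once, and a read contributes to at
most one category.

- report gate: N + encompassing ≥ 2;
- ranking: SS desc, encompassing desc, Q desc, then (gene5, gene3) for
  determinism;
- final filter (disjunctive): total < 5, or SS < 1, or *both* breakpoint
  sides flagged repeat/self-chain. The legacy stricter rule — any flagged
  side removes the candidate unless encompassing pairs corroborate it — is
  available as `v1_repeat_rescue` and off by default;
- isoform merge: candidates sharing the *oriented* (gene5, gene3) pair
  collapse to the best-ranked junction, all isoform breakpoints retained in
  an auxiliary report column. Swapped orientations are distinct fusions;
- classification: Intra iff both breakpoints share a chromosome. Frame uses
  the longest-CDS transcript per gene: with r = coding bases retained in
  the 5' partner (breakpoint base included) and s = coding bases skipped in
  the 3' partner (breakpoint base is the first retained), the call is IF
  iff r ≡ s (mod 3); NA if either breakpoint lies outside an annotated CDS.
  "Total supporting reads" counts an encompassing pair as one unit, so
  Total = Sp + Enc in the report.

## The synthetic world

The generator emulates a bulk 2×100 bp experiment: insert length
Normal(250, 30) truncated to [read length, transcript length], substitution
errors at 10⁻³, coverage 30× (fusion transcripts scaled by
`expression_depth`). The genome has a 700 kb and a 60 kb chromosome with
six forward-strand genes (2–5 exons of 150–400 nt, introns 200–800 nt,
30 nt UTRs, CDS length a multiple of 3) placed in evenly spaced slots;
chr1's size is chosen so same-chromosome slots are farther apart than
`max_intron`, making an intra-chromosomal fusion between them genuinely
chimeric/discordant to the scan. A 300 nt motif tiled on every chromosome
provides the repeat track; a 400 nt block copied across chromosomes
provides the self-chain track.

Auto-chosen fusion breakpoints sit mid-CDS with ≥ 25 nt of exon margin and
are constrained to have *no* junction microhomology (the base after either
breakpoint must mismatch the partner continuation), so the planted junction
is genomically unambiguous and exact breakpoint recovery is a fair
requirement. Explicit breakpoints bypass this constraint (and must be
exonic).

The idealised mapper writes alignments by construction from the truth:
spliced N-CIGAR proper pairs for ordinary reads; a soft-clipped primary
plus SA-linked supplementary for junction-crossing reads with ≥ 20 nt
anchored on both sides; a clipped primary only (partial alignment) when one
anchor is 1–19 nt — below a practical seed limit a real mapper would place
the whole read as unmapped or partial; discordant flags for
junction-straddling pairs.

Features of real data deliberately *not* emulated: mapper noise and
multi-mapping, indels, quality-dependent errors, PCR duplicates, antisense
and overlapping genes, alternative isoforms, expression heterogeneity, and
intronic/intergenic breakpoints. A green end-to-end test therefore
establishes the correctness of the caller's logic on ideal evidence — not
its sensitivity or precision on clinical libraries, which the original
validation measured on patient data this package does not ship.

## Determinism

Every stage is a pure function of its inputs: simulator substreams are
seeded per stage, assembly output ordering is defined, chaining and ranking
ties are broken structurally, and per-region assembly gives identical
results for any worker-pool size. Two runs on identical inputs produce
byte-identical reports.

## Known limitations

- Contig re-alignment is splice-unaware: a contig spanning several exons
  aligns as one segment per exon, relying on chaining to stitch them; very
  short exons (< seed length) at a junction can shift evidence to the
  neighbouring exon.
- The negative-strand transcript projection in the simulator is not
  implemented (the data model and detector handle either strand; the
  generator's stated world is forward-stranded).
- Frame classification trusts the annotated CDS of the longest coding
  transcript; fusions preserving frame only on a minor isoform are labelled
  from the major one.
- The assembler targets junction contigs from hundreds of reads; it is not
  meant for whole-transcriptome input.
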