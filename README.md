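# refusion

Gene-fusion detection from paired-end RNA-seq alignments, with a built-in
deterministic simulator so every stage can be exercised without restricted
patient data.

Fusion transcripts — chimeric mRNAs joining exons of two different genes —
are recurrent drivers in many cancers (EML4–ALK in lung adenocarcinoma being
the classic example). `refusion` calls them from the alignment signatures a
split-aware spliced mapper leaves behind: soft-clipped partial alignments,
chimeric (supplementary) segments, and discordant read pairs. It is a
library: the importable API plus the narrative scripts under `examples/` are
the interface.

## Method

Detection proceeds in four stages.

1. **Relaxed breakpoint scan.** A read *X* of length *l* calls a potential
   breakpoint if (i) it maps chimerically; (ii) it is partially aligned
   with a discordant mate, its unmapped part is at least
   clamp(*l*/5, *kmer*, 3·*kmer*/2) nt with no undecided bases, and ≥ t₁
   (default 2) other discordant alignments within ±200 bp are consistent
   with it; (iii) as (ii) with a shorter unmapped part and ≥ t₂ (default 3)
   consistent neighbours; or (iv) ≥ t₃ (default 4) entirely aligned
   discordant pairs agree on one fusion point, the call sitting where their
   3' ends extend farthest. Calls within 200 bp are grouped (repeat-region
   calls removed first) and each group becomes a ±250 bp candidate region.
2. **Regional assembly.** Abnormal read pairs (discordant, singleton,
   partial/chimeric) anchored in each region are assembled by an internal
   single-k de Bruijn assembler (k = 21, coverage pruning, tip clipping)
   into junction contigs.
3. **Re-alignment and chaining.** Contigs are re-aligned to the genome by
   seed-and-extend; non-unique segment hits are removed; the remaining
   partial alignments are chained into best and second-best concatenated
   paths with aggregate scores q₁, q₂ for a contig of length q₀, giving

   Q = e^((q₁−q₀)/10) − e^((q₂−q₀)/10).

   A best path splitting between two different genes with ≤ 15 nt of contig
   overlap (microhomology) is a putative fusion junction; junctions in
   repeat or self-chain regions are flagged.
4. **Support, scoring and filtering.** Improperly aligned pairs re-aligned
   to the junction contig count as *spanning* (crossing the fusion point
   with ≥ 13 nt on both sides) or *encompassing* (mates on opposite sides),
   non-redundantly. Junctions with ≥ 2 supporting reads are ranked by the
   Spanning Score

   SS = N − Σᵢ |Lᵢ−Rᵢ| / (Lᵢ+Rᵢ)

   over the N spanning reads with side lengths Lᵢ, Rᵢ, then by encompassing
   pairs, then by Q. A final filter removes candidates with < 5 total
   supporting reads, SS < 1, or both breakpoints in repeat/self-chain
   regions; isoform junctions of the same oriented gene pair are merged,
   and calls are labelled Intra/Inter-chromosomal and in-frame (IF) /
   out-of-frame (OF) from the gene models' CDS.

The simulator (`refusion.synthetic_data`) generates toy genomes, gene
models, planted fusions with machine-readable truth, 2×100 bp read pairs
and idealised mapper output, all as a pure function of one seed.

## Worked example

```bash
python examples/01_simulate_fusion_reads.py
python examples/02_detect_fusions.py
```

prints (seed 7):

```
stage counts: {'calls': 72, 'groups': 5, 'regions': 5, 'contigs': 5,
               'junction_candidates': 2, 'reported': 2}
rank gene5->gene3  breakpoints (1-based)          Sp Enc  SS    Q    type frame
   1 G1->G3   chr1:3459 | chr1:234587   30  20 18.74  1.00 Intra IF
   2 G2->G5   chr2:3671 | chr1:466864   29  17 16.90  1.00 Inter OF
```

Both planted fusions are recovered at their exact breakpoints. `Sp`/`Enc`
are the non-redundant spanning and encompassing counts (Total = Sp + Enc);
`SS` near `Sp` means the junction reads are well balanced around the fusion
point; `Q = 1.00` means the contig has a single, unambiguous genome
mapping. `examples/03_scores_by_hand.py` and `examples/04_regional_assembly.py`
demonstrate the scores and the assembler in isolation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's operating thresholds from scratch by sweeping
constructed inputs through the package — the minimum aligned length for a
spanning read, the final filter's support and Spanning Score cut-offs, the
breakpoint grouping distance, and the junction microhomology tolerance —
and writes the observed transition points as JSON.
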