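"""Simulate a toy RNA-seq experiment with two planted gene fusions.

Builds a two-chromosome genome with six multi-exon genes, joins G1->G3
(same chromosome, in frame) and G2->G5 (across chromosomes, out of frame),
draws 2x100 bp read pairs, and writes mapper-like SAM plus ground truth.
"""

from pathlib import Path

from refusion.synthetic_data import FusionSpec, SimConfig, simulate

outdir = Path("scratch/example_sim")
config = SimConfig(seed=7, fusion_specs=[
    FusionSpec("G1", "G3", frame="IF"),
    FusionSpec("G2", "G5", frame="OF"),
])
sim = simulate(config, outdir)

print(f"wrote {len(sim.pairs)} read pairs to {outdir}/")
print("planted fusions (1-based breakpoints):")
for t in sim.truths:
    print(f"  {t.gene5}->{t.gene3}  {t.chrom5}:{t.pos5 + 1} | "
          f"{t.chrom3}:{t.pos3 + 1}  {t.type}/{t.frame}")
# Each line is one fused transcript: the 5' partner's exons up to the first
# breakpoint spliced onto the 3' partner's exons from the second breakpoint.
# Intra/Inter says whether both breakpoints share a chromosome; IF/OF says
# whether the fused coding sequences stay in one reading frame.
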