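"""Run the full fusion-detection pipeline on simulated reads.

Scans alignments for chimeric/partial/discordant evidence, assembles each
breakpoint neighbourhood, re-aligns contigs to the genome, and prints the
ranked fusion report.  Run 01_simulate_fusion_reads.py first, or let this
script simulate its own input.
"""

from pathlib import Path

from refusion.pipeline import detect
from refusion.synthetic_data import FusionSpec, SimConfig, simulate

outdir = Path("scratch/example_sim")
if not (outdir / "aln.sam").exists():
    simulate(SimConfig(seed=7, fusion_specs=[
        FusionSpec("G1", "G3", frame="IF"),
        FusionSpec("G2", "G5", frame="OF")]), outdir)

result = detect(bam=outdir / "aln.sam", ref=outdir / "genome.fa",
                genes=outdir / "genes.gtf",
                repeats=outdir / "repeats.bed",
                selfchain=outdir / "selfchain.bed",
                out=outdir / "report.tsv")

print("stage counts:", result.counts)
print("rank gene5->gene3  breakpoints (1-based)          Sp Enc  SS    Q    "
      "type frame")
for rank, c in enumerate(result.candidates, 1):
    j = c.junction
    print(f"{rank:4d} {j.gene5}->{j.gene3:4s} "
          f"{j.break5.chrom}:{j.break5.pos + 1} | "
          f"{j.break3.chrom}:{j.break3.pos + 1}  "
          f"{c.spanning.n:3d} {c.encompassing:3d} {c.ss:5.2f} {c.q:5.2f} "
          f"{c.type:5s} {c.frame}")
# Sp counts independent reads crossing the junction with >= 13 nt anchored
# on both sides; Enc counts pairs whose mates flank the junction without
# crossing it.  SS rewards many well-balanced junction reads; Q near 1 means
# the contig has one dominant genome mapping (no good alternative).
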