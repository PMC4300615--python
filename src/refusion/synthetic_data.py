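"""Deterministic simulator of toy genomes, planted fusions and mapper output.

The generator emulates a bulk paired-end RNA-seq experiment (2 x 100 bp,
~250 bp inserts) over a small multi-chromosome genome with annotated
multi-exon genes, a planted repeat track and a self-chain-like duplication.
Fusion transcripts splice the 5' portion of one gene to the 3' portion of
another at exonic breakpoints; reads are drawn from wild-type and fused
transcripts and written as the idealised alignments a split-aware mapper
would report: proper pairs for ordinary reads, soft-clipped primary plus
linked supplementary segments for junction-crossing reads, discordant flags
for junction-straddling pairs, and unmapped records for reads whose anchor
on one side is below the mapper's practical limit.

Every artifact is a pure function of the seed; each stage draws from its own
seeded substream so stages are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .io_model import Gene, GeneModel, IntervalSet, Transcript, revcomp

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FusionSpec:
    """One planted fusion: 5' gene joined to 3' gene at exonic breakpoints.

    Breakpoints may be given explicitly (0-based genomic: last retained base
    of the 5' gene, first retained base of the 3' gene) or left None, in
    which case mid-CDS positions are chosen to realise ``frame`` with no
    microhomology at the junction.
    """

    gene5: str
    gene3: str
    breakpoint5: Optional[int] = None
    breakpoint3: Optional[int] = None
    frame: str = "IF"  # IF or OF, used when breakpoints are None
    expression_depth: float = 1.0


@dataclass
class SimConfig:
    seed: int = 0
    # chr1 is sized so same-chromosome gene slots lie farther apart than the
    # 200 kb maximum intron length: an intra-chromosomal fusion between them
    # produces genuinely chimeric/discordant evidence
    chrom_lengths: tuple = (700_000, 60_000)
    n_genes: int = 6
    fusion_specs: list = field(default_factory=list)
    read_len: int = 100
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    error_rate: float = 0.001
    coverage: float = 30.0
    exon_count_range: tuple = (2, 5)
    exon_len_range: tuple = (150, 400)
    intron_len_range: tuple = (200, 800)
    utr_len: int = 30
    repeat_track: bool = True
    selfchain_track: bool = True
    min_anchor: int = 20  # mapper limit: shorter junction anchors go unmapped
    partial_only: bool = False  # emit split reads without supplementary

    def __post_init__(self) -> None:
        if any(l < 10_000 for l in self.chrom_lengths):
            raise ValueError("chromosomes must be >= 10 kb")


@dataclass
class SimWorld:
    genome: dict  # chrom -> str
    model: GeneModel
    repeats: IntervalSet
    selfchain: IntervalSet
    chrom_lengths: dict


@dataclass
class FusionTruth:
    gene5: str
    gene3: str
    chrom5: str
    pos5: int  # 0-based, last retained base of the 5' partner
    strand5: str
    chrom3: str
    pos3: int  # 0-based, first retained base of the 3' partner
    strand3: str
    type: str  # Intra / Inter
    frame: str  # IF / OF / NA
    fused_id: str = ""
    junction_offset: int = 0  # junction position on the fused transcript
    fused_seq: str = ""
    junction_seq: str = ""
    expression_depth: float = 1.0


@dataclass
class TxPart:
    fx_start: int
    fx_end: int
    transcript: Transcript
    src_offset: int  # source transcript offset at fx_start


@dataclass
class TxMap:
    tx_id: str
    parts: list
    length: int

    def plans(self, a: int, b: int) -> list[dict]:
        """Per-locus alignment plans for fused-transcript interval [a, b):
        genomic blocks plus soft-clip lengths in reference orientation."""
        out = []
        for part in self.parts:
            lo, hi = max(a, part.fx_start), min(b, part.fx_end)
            if hi <= lo:
                continue
            src_lo = part.src_offset + (lo - part.fx_start)
            src_hi = part.src_offset + (hi - part.fx_start)
            blocks = part.transcript.project(src_lo, src_hi)
            out.append({
                "chrom": part.transcript.chrom,
                "blocks": blocks,
                "clip_left": lo - a,
                "clip_right": b - hi,
                "aligned": hi - lo,
            })
        return out


@dataclass
class ReadPair:
    read_id: str
    tx_id: str
    start: int  # fragment interval on the transcript
    end: int
    seq1: str  # read orientation (read2 is the reverse complement strand)
    seq2: str


@dataclass
class SimResult:
    config: SimConfig
    world: SimWorld
    truths: list
    txmaps: dict
    pairs: list
    outdir: Path
    fasta_path: Path
    gtf_path: Path
    repeats_path: Path
    selfchain_path: Path
    fastq1_path: Path
    fastq2_path: Path
    sam_path: Path
    truth_path: Path


# ---------------------------------------------------------------------------
# genome and gene model


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def make_genome(config: SimConfig,
                rng: Optional[np.random.Generator] = None) -> SimWorld:
    """Generate chromosome sequences, non-overlapping multi-exon genes with
    CDS, a planted repeat track (a fixed 300 nt motif tiled on every
    chromosome) and a self-chain-like cross-chromosome duplication."""
    rng = rng or np.random.default_rng([config.seed, 0])
    chroms = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    lengths = dict(zip(chroms, config.chrom_lengths))
    arrays = {c: _random_seq(rng, n) for c, n in lengths.items()}

    repeat_ivs = []
    if config.repeat_track:
        motif = _random_seq(rng, 300)
        for c in chroms:
            for start in (500, 810):
                arrays[c][start:start + 300] = motif
                repeat_ivs.append((c, start, start + 300))
    selfchain_ivs = []
    if config.selfchain_track and len(chroms) > 1:
        block = arrays[chroms[0]][1200:1600].copy()
        selfchain_ivs.append((chroms[0], 1200, 1600))
        for c in chroms[1:]:
            arrays[c][1200:1600] = block
            selfchain_ivs.append((c, 1200, 1600))

    # genes round-robin over chromosomes, spread evenly so intra-chromosomal
    # fusion partners can sit farther apart than the maximum intron length
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]].append(f"G{i + 1}")
    genes = []
    lo_ex, hi_ex = config.exon_count_range
    for c in chroms:
        ids = per_chrom[c]
        if not ids:
            continue
        usable = lengths[c] - 5000
        slot = usable // max(1, len(ids))
        cursor_limit = 0
        for k, gid in enumerate(ids):
            start = 2500 + k * slot
            n_ex = int(rng.integers(lo_ex, hi_ex + 1))
            ex_lens = rng.integers(*config.exon_len_range, n_ex)
            in_lens = rng.integers(*config.intron_len_range,
                                   max(0, n_ex - 1))
            exons = []
            pos = start
            for j in range(n_ex):
                exons.append((pos, pos + int(ex_lens[j])))
                pos = exons[-1][1] + (int(in_lens[j]) if j < n_ex - 1 else 0)
            if pos > lengths[c] - 500 or start < cursor_limit:
                raise ValueError(
                    f"cannot place gene {gid} on {c}; enlarge chromosomes")
            cursor_limit = pos + 200
            tx = Transcript(id=f"{gid}.t1", gene_id=gid, chrom=c, strand="+",
                            exons=exons)
            total = tx.tx_len
            cds_len = 3 * ((total - 2 * config.utr_len) // 3)
            cds_blocks = []
            if cds_len >= 3:
                off = config.utr_len
                cds_blocks = tx.project(off, off + cds_len)
            tx.cds = sorted(cds_blocks)
            gene = Gene(id=gid, name=gid, chrom=c, strand="+",
                        start=exons[0][0], end=exons[-1][1])
            gene.transcripts[tx.id] = tx
            genes.append(gene)
    genome = {c: arr.tobytes().decode("ascii") for c, arr in arrays.items()}
    return SimWorld(genome=genome, model=GeneModel(genes),
                    repeats=IntervalSet(repeat_ivs, label="repeat"),
                    selfchain=IntervalSet(selfchain_ivs, label="selfchain"),
                    chrom_lengths=lengths)


# ---------------------------------------------------------------------------
# fusion planting


def _pick_breakpoint(tx: Transcript, genome: dict, want_offset: int,
                     margin: int = 25, step: int = 3) -> Optional[int]:
    """Coding offset near ``want_offset`` whose genomic base keeps ``margin``
    nt of exon on both sides; stepping preserves codon phase."""
    for delta in range(0, tx.cds_len, step):
        for cand in (want_offset + delta, want_offset - delta):
            if not 0 <= cand < tx.cds_len:
                continue
            pos = tx.coding_pos(cand)
            for s, e in tx.exons:
                if s <= pos < e:
                    if pos - s >= margin and e - pos > margin:
                        return cand
                    break
    return None


def plant_fusions(world: SimWorld, config: SimConfig,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[list[FusionTruth], dict]:
    """Create fused transcripts and truth records for every fusion spec.

    The fused transcript is the spliced 5' portion of geneA up to (and
    including) breakpointA followed by the spliced 3' portion of geneB from
    breakpointB onward.  Auto-chosen breakpoints avoid junction microhomology
    (the genomic continuation past either breakpoint must mismatch the fused
    sequence) so the junction is genomically unambiguous.
    """
    del rng  # breakpoint choice is deterministic given the genome
    truths: list[FusionTruth] = []
    txmaps: dict[str, TxMap] = {}
    for k, spec in enumerate(config.fusion_specs):
        g5 = world.model.genes.get(spec.gene5)
        g3 = world.model.genes.get(spec.gene3)
        if g5 is None or g3 is None:
            raise ValueError(f"fusion spec references unknown gene: {spec}")
        t5 = g5.longest_cds_transcript() or next(iter(g5.transcripts.values()))
        t3 = g3.longest_cds_transcript() or next(iter(g3.transcripts.values()))
        if spec.breakpoint5 is not None:
            p5 = spec.breakpoint5
            if t5.tx_offset(p5) is None:
                raise ValueError(f"breakpoint {p5} not exonic in {t5.id}")
            if spec.breakpoint3 is None:
                raise ValueError("both breakpoints must be given together")
            p3 = spec.breakpoint3
            if t3.tx_offset(p3) is None:
                raise ValueError(f"breakpoint {p3} not exonic in {t3.id}")
        else:
            p5, p3 = _choose_breakpoints(t5, t3, world.genome, spec.frame)
        off5 = t5.coding_offset(p5)
        off3 = t3.coding_offset(p3)
        if off5 is None or off3 is None:
            frame = "NA"
        else:
            frame = "IF" if ((off5 + 1) - off3) % 3 == 0 else "OF"
        seq5 = t5.spliced_seq(world.genome)
        seq3 = t3.spliced_seq(world.genome)
        jx = t5.tx_offset(p5) + 1
        o3 = t3.tx_offset(p3)
        fused_seq = seq5[:jx] + seq3[o3:]
        fused_id = f"fusion{k + 1}_{spec.gene5}_{spec.gene3}"
        txmaps[fused_id] = TxMap(
            tx_id=fused_id,
            parts=[TxPart(0, jx, t5, 0),
                   TxPart(jx, len(fused_seq), t3, o3)],
            length=len(fused_seq))
        truths.append(FusionTruth(
            gene5=spec.gene5, gene3=spec.gene3,
            chrom5=g5.chrom, pos5=p5, strand5=g5.strand,
            chrom3=g3.chrom, pos3=p3, strand3=g3.strand,
            type="Intra" if g5.chrom == g3.chrom else "Inter",
            frame=frame, fused_id=fused_id, junction_offset=jx,
            fused_seq=fused_seq,
            junction_seq=fused_seq[max(0, jx - 50):jx + 50],
            expression_depth=spec.expression_depth))
    return truths, txmaps


def _choose_breakpoints(t5: Transcript, t3: Transcript, genome: dict,
                        frame: str) -> tuple[int, int]:
    """Mid-CDS breakpoints realising the requested frame with no junction
    microhomology against either genomic continuation."""
    g5seq = genome[t5.chrom]
    g3seq = genome[t3.chrom]
    off5 = _pick_breakpoint(t5, genome, t5.cds_len // 2)
    if off5 is None:
        raise ValueError(f"no usable breakpoint in {t5.id}")
    p5 = t5.coding_pos(off5)
    want_phase = (off5 + 1) % 3 if frame == "IF" else (off5 + 1 + 2) % 3
    target = t3.cds_len // 2
    target += (want_phase - target) % 3
    for delta in range(0, t3.cds_len, 3):
        for cand in (target + delta, target - delta):
            if not 3 <= cand < t3.cds_len - 3:
                continue
            pos = t3.coding_pos(cand)
            inside = any(s + 25 <= pos < e - 25 for s, e in t3.exons)
            if not inside:
                continue
            # no microhomology: first 3' base must differ from the 5'
            # genomic continuation, and vice versa
            if g3seq[pos] == g5seq[p5 + 1]:
                continue
            if g5seq[p5] == g3seq[pos - 1]:
                continue
            return p5, pos
    raise ValueError(f"no usable breakpoint in {t3.id}")


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(world: SimWorld, truths: list, txmaps: dict,
                   config: SimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[list[ReadPair], dict]:
    """Draw paired reads from wild-type and fused transcripts.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated to
    [read_len, transcript length]; substitution errors at ``error_rate``;
    read ids encode the originating transcript and fragment for debugging.
    Returns the pairs and the full transcript-map registry (wild-type maps
    included) for alignment emission.
    """
    rng = rng or np.random.default_rng([config.seed, 2])
    registry = dict(txmaps)
    jobs = []
    for gene in sorted(world.model.genes.values(), key=lambda g: g.id):
        tx = next(iter(sorted(gene.transcripts)))
        tx = gene.transcripts[tx]
        registry[tx.id] = TxMap(tx_id=tx.id,
                                parts=[TxPart(0, tx.tx_len, tx, 0)],
                                length=tx.tx_len)
        jobs.append((tx.id, tx.spliced_seq(world.genome), config.coverage))
    for t in truths:
        jobs.append((t.fused_id, t.fused_seq,
                     config.coverage * t.expression_depth))
    rl = config.read_len
    pairs: list[ReadPair] = []
    for tx_id, seq, cov in jobs:
        tx_len = len(seq)
        if tx_len < rl:
            logger.warning("transcript %s shorter than read length; skipped",
                           tx_id)
            continue
        n_pairs = int(round(cov * tx_len / (2.0 * rl)))
        if n_pairs <= 0:
            continue
        frags = rng.normal(config.insert_mean, config.insert_sd, n_pairs)
        frags = np.clip(np.rint(frags).astype(int), rl, tx_len)
        starts = (rng.random(n_pairs) * (tx_len - frags + 1)).astype(int)
        for i in range(n_pairs):
            s, fl = int(starts[i]), int(frags[i])
            e = s + fl
            r1 = seq[s:s + rl]
            r2 = revcomp(seq[e - rl:e])
            r1 = _add_errors(r1, config.error_rate, rng)
            r2 = _add_errors(r2, config.error_rate, rng)
            pairs.append(ReadPair(
                read_id=f"sim|{tx_id}|{s}-{e}|{i}",
                tx_id=tx_id, start=s, end=e, seq1=r1, seq2=r2))
    return pairs, registry


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# idealised mapper


def _cigar(plan: dict) -> str:
    ops = []
    if plan["clip_left"]:
        ops.append(f"{plan['clip_left']}S")
    blocks = plan["blocks"]
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            ops.append(f"{gap}N")
        ops.append(f"{e - s}M")
    if plan["clip_right"]:
        ops.append(f"{plan['clip_right']}S")
    return "".join(ops)


def emit_alignments(world: SimWorld, pairs: list, registry: dict,
                    config: SimConfig, path) -> None:
    """Write the idealised, coordinate-sorted SAM for all simulated pairs.

    Alignment is by construction from the simulation truth: reads fully
    inside one gene locus become (spliced) proper-pair records;
    junction-crossing reads become a soft-clipped primary plus a linked
    supplementary segment on the partner locus (or, below the anchor limit,
    an unmapped record); junction-straddling pairs carry discordant flags.
    """
    chroms = sorted(world.chrom_lengths)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": world.chrom_lengths[c]} for c in chroms],
    })
    tid = {c: i for i, c in enumerate(chroms)}
    records = []
    for pair in sorted(pairs, key=lambda p: p.read_id):
        txmap = registry[pair.tx_id]
        rl = config.read_len
        ends = [(1, pair.start, pair.start + rl, False, pair.seq1),
                (2, pair.end - rl, pair.end, True, pair.seq2)]
        placed = {}
        for endno, a, b, is_rev, seq in ends:
            plans = txmap.plans(a, b)
            usable = [p for p in plans if p["aligned"] >= config.min_anchor]
            if len(plans) > 1 and (len(usable) < len(plans)
                                   or config.partial_only):
                # split read with a sub-anchor part, or partial-only mode:
                # keep only the longest part as a clipped primary
                usable = [max(plans, key=lambda p: p["aligned"])] \
                    if usable else []
            placed[endno] = usable
        one_part = any(part.fx_start <= pair.start and pair.end <= part.fx_end
                       for part in txmap.parts)
        proper = one_part and all(len(placed[e]) == 1 for e in (1, 2))
        for endno, a, b, is_rev, seq in ends:
            mate_no = 2 if endno == 1 else 1
            mate_plans = placed[mate_no]
            mate_rev = mate_no == 2
            plans = placed[endno]
            ref_seq = revcomp(seq) if is_rev else seq
            if not plans:
                records.append(_unmapped_record(
                    header, tid, pair, endno, seq,
                    mate_plans[0] if mate_plans else None, mate_rev))
                continue
            plans = sorted(plans, key=lambda p: -p["aligned"])
            for rank, plan in enumerate(plans):
                rec = pysam.AlignedSegment(header)
                rec.query_name = pair.read_id
                rec.reference_id = tid[plan["chrom"]]
                rec.reference_start = plan["blocks"][0][0]
                rec.mapping_quality = 60
                rec.cigarstring = _cigar(plan)
                rec.query_sequence = ref_seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(ref_seq))
                rec.is_paired = True
                rec.is_read1 = endno == 1
                rec.is_read2 = endno == 2
                rec.is_reverse = is_rev
                rec.is_proper_pair = proper
                rec.is_supplementary = rank > 0
                if mate_plans:
                    mp = mate_plans[0]
                    rec.next_reference_id = tid[mp["chrom"]]
                    rec.next_reference_start = mp["blocks"][0][0]
                    rec.mate_is_reverse = mate_rev
                else:
                    rec.mate_is_unmapped = True
                    rec.next_reference_id = rec.reference_id
                    rec.next_reference_start = rec.reference_start
                if len(plans) > 1:
                    other = plans[1 - rank]
                    strand = "-" if is_rev else "+"
                    rec.set_tag("SA", f"{other['chrom']},"
                                f"{other['blocks'][0][0] + 1},{strand},"
                                f"{_cigar(other)},60,0;")
                records.append(rec)
    records.sort(key=lambda r: (r.reference_id if r.reference_id >= 0
                                else len(chroms),
                                r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def _unmapped_record(header, tid, pair, endno, seq, mate_plan, mate_rev):
    rec = pysam.AlignedSegment(header)
    rec.query_name = pair.read_id
    rec.is_paired = True
    rec.is_read1 = endno == 1
    rec.is_read2 = endno == 2
    rec.is_unmapped = True
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if mate_plan is not None:
        rec.next_reference_id = tid[mate_plan["chrom"]]
        rec.next_reference_start = mate_plan["blocks"][0][0]
        rec.mate_is_reverse = mate_rev
        # convention: place the unmapped read at its mate's coordinate
        rec.reference_id = rec.next_reference_id
        rec.reference_start = rec.next_reference_start
    else:
        rec.mate_is_unmapped = True
    return rec


# ---------------------------------------------------------------------------
# file output and orchestration


def _write_fasta(genome: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_gtf(model: GeneModel, path: Path) -> None:
    lines = []
    for gid in sorted(model.genes):
        g = model.genes[gid]
        attrs = f'gene_id "{g.id}";'
        lines.append("\t".join([g.chrom, "refusion_sim", "gene",
                                str(g.start + 1), str(g.end), ".", g.strand,
                                ".", attrs]))
        for tid in sorted(g.transcripts):
            tx = g.transcripts[tid]
            tattrs = f'gene_id "{g.id}"; transcript_id "{tx.id}";'
            lines.append("\t".join([g.chrom, "refusion_sim", "transcript",
                                    str(tx.exons[0][0] + 1),
                                    str(tx.exons[-1][1]), ".", g.strand, ".",
                                    tattrs]))
            for s, e in tx.exons:
                lines.append("\t".join([g.chrom, "refusion_sim", "exon",
                                        str(s + 1), str(e), ".", g.strand,
                                        ".", tattrs]))
            cum = 0
            for s, e in tx.cds:
                phase = (3 - cum % 3) % 3
                lines.append("\t".join([g.chrom, "refusion_sim", "CDS",
                                        str(s + 1), str(e), ".", g.strand,
                                        str(phase), tattrs]))
                cum += e - s
    Path(path).write_text("\n".join(lines) + "\n")


def _write_bed(ivset: IntervalSet, chroms, path: Path) -> None:
    lines = []
    for chrom in sorted(chroms):
        for s, e in ivset.intervals(chrom):
            lines.append(f"{chrom}\t{s}\t{e}\t{ivset.label}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_fastq(pairs: list, path1: Path, path2: Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def _write_truth(truths: list, path: Path) -> None:
    cols = ["gene5", "gene3", "chrom5", "pos5", "strand5", "chrom3", "pos3",
            "strand3", "type", "frame", "fused_id", "junction_seq"]
    lines = ["\t".join(cols)]
    for t in truths:
        lines.append("\t".join(str(x) for x in [
            t.gene5, t.gene3, t.chrom5, t.pos5 + 1, t.strand5,
            t.chrom3, t.pos3 + 1, t.strand3, t.type, t.frame,
            t.fused_id, t.junction_seq]))
    Path(path).write_text("\n".join(lines) + "\n")


def simulate(config: SimConfig, outdir) -> SimResult:
    """Run the whole generator and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = make_genome(config, np.random.default_rng([config.seed, 0]))
    truths, txmaps = plant_fusions(world, config,
                                   np.random.default_rng([config.seed, 1]))
    pairs, registry = simulate_reads(world, truths, txmaps, config,
                                     np.random.default_rng([config.seed, 2]))
    paths = {
        "fasta_path": outdir / "genome.fa",
        "gtf_path": outdir / "genes.gtf",
        "repeats_path": outdir / "repeats.bed",
        "selfchain_path": outdir / "selfchain.bed",
        "fastq1_path": outdir / "reads_1.fastq",
        "fastq2_path": outdir / "reads_2.fastq",
        "sam_path": outdir / "aln.sam",
        "truth_path": outdir / "truth.tsv",
    }
    _write_fasta(world.genome, paths["fasta_path"])
    _write_gtf(world.model, paths["gtf_path"])
    chroms = list(world.chrom_lengths)
    _write_bed(world.repeats, chroms, paths["repeats_path"])
    _write_bed(world.selfchain, chroms, paths["selfchain_path"])
    _write_fastq(pairs, paths["fastq1_path"], paths["fastq2_path"])
    emit_alignments(world, pairs, registry, config, paths["sam_path"])
    _write_truth(truths, paths["truth_path"])
    return SimResult(config=config, world=world, truths=truths,
                     txmaps=registry, pairs=pairs, outdir=outdir, **paths)
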