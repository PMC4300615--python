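"""Contig re-alignment, chaining, and two-gene junction identification.

Assembled junction contigs are aligned back to the reference genome with a
seed-and-extend local aligner (match +1, mismatch -1, ungapped extension;
chaining supplies the gaps).  Non-unique segment hits — contig intervals
mapping to more than one genomic locus within 95% of the best score — are
removed.  The remaining partial alignments are concatenated by dynamic
programming into the best and second-best chains with aggregate scores q1
and q2; for a contig of length q0 the alignment score is

    Q = exp((q1 - q0)/10) - exp((q2 - q0)/10)

with the second term zero when no alternative chain exists.  A chain whose
best path splits, with at most 15 nt of contig overlap (microhomology),
between two different genes is a putative fusion junction; its breakpoints
are flagged when they fall in repeat or self-chain regions.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io_model import GeneModel, IntervalSet, ScanConfig, revcomp
from .regional_assembly import Contig


@dataclass
class SegmentAlignment:
    """A local alignment of contig[qstart:qend) to the genome."""

    qstart: int
    qend: int
    chrom: str
    gstart: int
    gend: int
    strand: str
    matches: int
    score: int

    def __post_init__(self) -> None:
        if self.qend <= self.qstart:
            raise ValueError("qend must exceed qstart")


@dataclass
class Breakend:
    chrom: str
    pos: int  # 0-based position of the junction-adjacent aligned base
    strand: str


@dataclass
class ChainedAlignment:
    q0: int
    best_path: list = field(default_factory=list)
    q1: Optional[int] = None
    second_path: Optional[list] = None
    q2: Optional[int] = None

    @property
    def Q(self) -> float:
        if self.q1 is None:
            return 0.0
        q = math.exp((self.q1 - self.q0) / 10.0)
        if self.q2 is not None:
            q -= math.exp((self.q2 - self.q0) / 10.0)
        return q


@dataclass
class JunctionCandidate:
    contig: Contig
    gene5: str
    gene3: str
    break5: Breakend
    break3: Breakend
    contig_break: int
    chained: Optional[ChainedAlignment] = None
    flags: set = field(default_factory=set)

    @property
    def Q(self) -> float:
        return self.chained.Q if self.chained is not None else 0.0


# ---------------------------------------------------------------------------
# genome seed index and seed-and-extend alignment


_ENC = {c: i for i, c in enumerate("ACGT")}


class GenomeIndex:
    """Exact-seed index of a genome for contig re-alignment.

    Seeds are 2-bit encoded into a sorted int64 array; lookups binary-search
    the array, which keeps the index small enough to rebuild per run.
    """

    def __init__(self, sequences: dict[str, str], seed: int = 15):
        self.seed = seed
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self._chroms = sorted(self.sequences)
        lut = np.full(256, 255, dtype=np.int64)
        for b, v in zip(b"ACGT", range(4)):
            lut[b] = v
        codes_list, pos_list = [], []
        self._offsets = {}
        off = 0
        for c in self._chroms:
            s = self.sequences[c]
            self._offsets[c] = off
            arr = lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            n = len(arr) - seed + 1
            if n > 0:
                code = np.zeros(n, dtype=np.int64)
                ok = np.ones(n, dtype=bool)
                for j in range(seed):
                    window = arr[j:j + n]
                    code = code * 4 + np.where(window < 4, window, 0)
                    ok &= window < 4
                idx = np.nonzero(ok)[0]
                codes_list.append(code[idx])
                pos_list.append(idx + off)
            off += len(s)
        if codes_list:
            codes = np.concatenate(codes_list)
            pos = np.concatenate(pos_list)
        else:
            codes = np.empty(0, dtype=np.int64)
            pos = np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]
        self._chrom_starts = [self._offsets[c] for c in self._chroms]

    @classmethod
    def from_fasta(cls, path, seed: int = 15) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()}, seed=seed)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def hits(self, mer: str) -> list[tuple[str, int]]:
        code = 0
        for ch in mer:
            v = _ENC.get(ch)
            if v is None:
                return []
            code = code * 4 + v
        lo = np.searchsorted(self._codes, code, "left")
        hi = np.searchsorted(self._codes, code, "right")
        out = []
        for p in self._pos[lo:hi]:
            ci = bisect.bisect_right(self._chrom_starts, int(p)) - 1
            chrom = self._chroms[ci]
            out.append((chrom, int(p) - self._offsets[chrom]))
        out.sort()
        return out


def _extend(contig: str, genome: str, qpos: int, gpos: int, seed: int,
            max_mismatch_run: int = 3) -> tuple[int, int, int, int]:
    """Ungapped extension of a seed match in both directions.

    Boundary placement maximises a strict running score (match +1, mismatch
    -2) and stops after a run of mismatches, so extension past a fusion
    junction needs better than a 2:1 match ratio; the returned ``score`` for
    chaining is the plain matches - mismatches of the final interval.
    Returns (qstart, qend, matches, score) with
    gstart = gpos - (qpos - qstart).
    """
    # right of the seed: take the prefix maximising the running score
    qe = qpos + seed
    best_s = cur_s = 0
    run = 0
    i, j = qpos + seed, gpos + seed
    while i < len(contig) and j < len(genome):
        if contig[i] == genome[j]:
            cur_s += 1
            run = 0
        else:
            cur_s -= 2
            run += 1
        i += 1
        j += 1
        if cur_s > best_s:
            qe, best_s = i, cur_s
        if run >= max_mismatch_run:
            break
    # left of the seed, symmetrically
    qs = qpos
    best_s = cur_s = 0
    run = 0
    i, j = qpos - 1, gpos - 1
    while i >= 0 and j >= 0:
        if contig[i] == genome[j]:
            cur_s += 1
            run = 0
        else:
            cur_s -= 2
            run += 1
        if cur_s > best_s:
            qs, best_s = i, cur_s
        if run >= max_mismatch_run:
            break
        i -= 1
        j -= 1
    # trim ends until the terminal window is an exact match, so chance
    # matches beyond a true junction cannot shift the segment boundary
    w = 6
    goff = gpos - qpos
    while qe - qs > w and any(contig[i] != genome[i + goff]
                              for i in range(qe - w, qe)):
        qe -= 1
    while qe - qs > w and any(contig[i] != genome[i + goff]
                              for i in range(qs, qs + w)):
        qs += 1
    m_b = sum(contig[i] == genome[i + goff] for i in range(qs, qe))
    s_b = 2 * m_b - (qe - qs)
    return qs, qe, m_b, s_b


def realign_contig(contig, genome: GenomeIndex,
                   min_seed: Optional[int] = None,
                   nonunique_frac: float = 0.95) -> list[SegmentAlignment]:
    """Seed-and-extend local alignments of a contig on both genome strands.

    Contig intervals mapping to more than one genomic locus with scores
    within ``nonunique_frac`` of the best are removed as non-unique.
    """
    seq = contig.seq if isinstance(contig, Contig) else str(contig)
    seq = seq.upper()
    seed = min_seed if min_seed is not None else genome.seed
    if len(seq) < seed:
        return []
    segments: list[SegmentAlignment] = []
    seen: set[tuple] = set()
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        step = max(1, seed // 3)
        positions = list(range(0, len(query) - seed + 1, step))
        if positions[-1] != len(query) - seed:
            positions.append(len(query) - seed)
        for qpos in positions:
            mer = query[qpos:qpos + seed]
            if "N" in mer:
                continue
            for chrom, gpos in genome.hits(mer):
                gseq = genome.sequences[chrom]
                qs, qe, matches, score = _extend(query, gseq, qpos, gpos, seed)
                gs = gpos - (qpos - qs)
                ge = gs + (qe - qs)
                if strand == "+":
                    cqs, cqe = qs, qe
                else:
                    cqs, cqe = len(seq) - qe, len(seq) - qs
                key = (cqs, cqe, chrom, gs, strand)
                if key in seen:
                    continue
                seen.add(key)
                segments.append(SegmentAlignment(
                    qstart=cqs, qend=cqe, chrom=chrom, gstart=gs, gend=ge,
                    strand=strand, matches=matches, score=score))
    segments = _drop_subsumed(segments)
    return _drop_nonunique(segments, nonunique_frac)


def _drop_subsumed(segments: list[SegmentAlignment]) -> list[SegmentAlignment]:
    """Keep one representative per (genomic locus) — the highest-scoring
    segment among those covering the same contig interval at the same
    genomic position."""
    segments.sort(key=lambda s: (-s.score, s.qstart, s.chrom, s.gstart))
    kept: list[SegmentAlignment] = []
    for s in segments:
        redundant = False
        for t in kept:
            if (s.chrom == t.chrom and s.strand == t.strand
                    and t.qstart <= s.qstart and s.qend <= t.qend
                    and s.gstart - s.qstart == t.gstart - t.qstart):
                redundant = True
                break
        if not redundant:
            kept.append(s)
    return kept


def _overlap_frac(a: SegmentAlignment, b: SegmentAlignment) -> float:
    inter = min(a.qend, b.qend) - max(a.qstart, b.qstart)
    union = max(a.qend, b.qend) - min(a.qstart, b.qstart)
    return inter / union if union > 0 else 0.0


def _drop_nonunique(segments: list[SegmentAlignment],
                    frac: float) -> list[SegmentAlignment]:
    """Remove segments whose contig interval also maps to a different
    genomic locus with a score within ``frac`` of the best."""
    out = []
    for s in segments:
        competitors = [t for t in segments if t is not s
                       and _overlap_frac(s, t) >= 0.9
                       and (t.chrom, t.gstart) != (s.chrom, s.gstart)]
        best_rival = max((t.score for t in competitors), default=None)
        if best_rival is not None:
            hi = max(s.score, best_rival)
            lo = min(s.score, best_rival)
            if lo >= frac * hi:
                continue
            if s.score < best_rival:
                continue
        out.append(s)
    out.sort(key=lambda s: (s.qstart, s.qend, s.chrom, s.gstart))
    return out


# ---------------------------------------------------------------------------
# chaining


def chain_paths(segments: list[SegmentAlignment], contig_len: int,
                max_overlap: int = 15) -> ChainedAlignment:
    """Concatenate partial alignments into the best and second-best chains.

    Consecutive chain members may overlap by at most ``max_overlap`` nt in
    contig coordinates (microhomology tolerance) and must advance along the
    contig; genomic jumps are free.  A segment's contribution is reduced by
    any contig overlap with its predecessor so the aggregate score never
    exceeds the contig length.
    """
    if not segments:
        return ChainedAlignment(q0=contig_len)
    segs = sorted(segments, key=lambda s: (s.qstart, s.qend, s.chrom, s.gstart))
    n = len(segs)
    # two-best DP: per segment keep the top-2 (score, path) ending there
    ending: list[list[tuple[int, tuple]]] = [[] for _ in range(n)]
    for i, s in enumerate(segs):
        cands = [(s.score, (i,))]
        for j in range(i):
            p = segs[j]
            ov = p.qend - s.qstart
            if ov > max_overlap or s.qend <= p.qend:
                continue
            gain = s.score - max(0, ov)
            for sc, path in ending[j]:
                cands.append((sc + gain, path + (i,)))
        cands.sort(key=lambda t: (-t[0], t[1]))
        ending[i] = cands[:2]
    pool = [(sc, path) for lst in ending for sc, path in lst]
    pool.sort(key=lambda t: (-t[0], t[1]))
    best_sc, best_path = pool[0]
    best_set = set(best_path)
    second = None
    for sc, path in pool[1:]:
        if set(path) != best_set:
            second = (sc, path)
            break
    chained = ChainedAlignment(
        q0=contig_len,
        best_path=[segs[i] for i in best_path],
        q1=min(best_sc, contig_len),
    )
    if second is not None:
        chained.second_path = [segs[i] for i in second[1]]
        chained.q2 = min(second[0], chained.q1)
    return chained


# ---------------------------------------------------------------------------
# junction detection


def _segment_gene(seg: SegmentAlignment, gene_model: GeneModel):
    genes = gene_model.query_interval(seg.chrom, seg.gstart, seg.gend)
    if not genes:
        return None
    # prefer the gene covering most of the segment
    def covered(g):
        return min(g.end, seg.gend) - max(g.start, seg.gstart)
    return max(genes, key=lambda g: (covered(g), g.id))


def _segment_gpos(seg: SegmentAlignment, p: int) -> int:
    """Genomic position of contig position ``p`` inside a segment."""
    if seg.strand == "+":
        return seg.gstart + (p - seg.qstart)
    return seg.gend - 1 - (p - seg.qstart)


def _refine_split(left: SegmentAlignment, right: SegmentAlignment,
                  contig_seq: str, genome: "GenomeIndex") -> int:
    """Contig split point inside the overlap of two partner segments that
    maximises total matched bases; resolves junction-adjacent homology."""
    lo = max(right.qstart, left.qstart + 1)
    hi = min(left.qend, right.qend - 1)
    if hi <= lo:
        return right.qstart
    gl = genome.sequences.get(left.chrom, "")
    gr = genome.sequences.get(right.chrom, "")

    def match(seg, gseq, p):
        g = _segment_gpos(seg, p)
        base = gseq[g] if 0 <= g < len(gseq) else "N"
        if seg.strand == "-":
            base = revcomp(base)
        return contig_seq[p] == base

    best_s, best_total = lo, -1
    for s in range(lo, hi + 1):
        total = sum(match(left, gl, p) for p in range(left.qstart, s)) \
            + sum(match(right, gr, p) for p in range(s, right.qend))
        if total > best_total:
            best_s, best_total = s, total
    return best_s


def detect_junction(chained: ChainedAlignment, contig, gene_model: GeneModel,
                    interval_sets: Iterable[IntervalSet] = (),
                    config: Optional[ScanConfig] = None,
                    genome: Optional[GenomeIndex] = None
                    ) -> Optional[JunctionCandidate]:
    """Identify a two-gene fusion junction in a contig's best chain.

    Returns a candidate when two consecutive best-path segments are assigned
    to different genes with contig overlap <= max_overlap; breakpoints sit at
    the facing segment ends.  When ``genome`` is supplied, the exact split
    inside an overlapping (microhomologous) junction is refined to the
    position maximising matched bases.  The 5' partner is the gene that is
    upstream in the fused transcript, resolved from segment and gene
    strands.  Repeat and self-chain flags are set per breakpoint side; low_Q
    flags a weak contig alignment.
    """
    config = config or ScanConfig()
    path = chained.best_path
    if not path or len(path) < 2:
        return None
    contig_seq = contig.seq if isinstance(contig, Contig) else str(contig)
    for left, right in zip(path, path[1:]):
        overlap = left.qend - right.qstart
        if overlap > config.max_overlap:
            continue
        gl = _segment_gene(left, gene_model)
        gr = _segment_gene(right, gene_model)
        if gl is None or gr is None or gl.id == gr.id:
            continue
        if genome is not None and overlap > 0:
            split = _refine_split(left, right, contig_seq, genome)
        else:
            split = right.qstart
        # facing ends: the junction-adjacent aligned base of each segment,
        # with overlapping bases beyond the split trimmed away
        left_end = max(split, left.qstart + 1)
        right_start = min(split, right.qend - 1)
        bl = Breakend(left.chrom, _segment_gpos(left, left_end - 1),
                      left.strand)
        br = Breakend(right.chrom, _segment_gpos(right, right_start),
                      right.strand)
        # orientation: contig read left-to-right equals fused-transcript
        # sense iff the left segment aligns on its gene's strand
        sense_left = left.strand == gl.strand
        sense_right = right.strand == gr.strand
        if sense_left or sense_right:
            gene5, gene3, b5, b3 = gl, gr, bl, br
        else:
            gene5, gene3, b5, b3 = gr, gl, br, bl
        flags: set[str] = set()
        for iv in interval_sets:
            label = iv.label or "region"
            if iv.query(b5.chrom, b5.pos):
                flags.add(f"{label}5")
            if iv.query(b3.chrom, b3.pos):
                flags.add(f"{label}3")
        if chained.Q < config.low_q:
            flags.add("low_Q")
        return JunctionCandidate(
            contig=contig, gene5=gene5.id, gene3=gene3.id,
            break5=b5, break3=b3, contig_break=split,
            chained=chained, flags=flags)
    return None
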