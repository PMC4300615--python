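"""Regional de novo assembly of abnormal read pairs around breakpoints.

Abnormal read pairs (discordant pairs, singletons, and reads with partial or
chimeric alignments) anchored in each candidate region are assembled with a
minimal single-k de Bruijn assembler: canonical k-mer counting, coverage
pruning, tip clipping, bubble popping by coverage, and maximal unbranched
path (unitig) extraction.  The goal is a contig spanning the fusion
junction, not a full transcriptome assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .breakpoint_scan import CandidateRegion, PairClass, classify_pair
from .io_model import AlignmentStore, ScanConfig, UnmappedStore, revcomp

logger = logging.getLogger(__name__)


@dataclass
class AnchoredReadSet:
    """Sequences of abnormal read pairs anchored in one candidate region."""

    region: CandidateRegion
    pairs: list = field(default_factory=list)  # (read_id, seq1|None, seq2|None)

    @property
    def sequences(self) -> list[str]:
        out = []
        for _rid, s1, s2 in self.pairs:
            if s1:
                out.append(s1)
            if s2:
                out.append(s2)
        return out


@dataclass
class Contig:
    seq: str  # canonical orientation (lexicographic min of seq/revcomp)
    k: int
    support: int
    region_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) < self.k:
            raise ValueError("contig shorter than k")


def extract_anchored_pairs(region: CandidateRegion,
                           alignment_store: AlignmentStore,
                           unmapped_store: Optional[UnmappedStore] = None,
                           config: Optional[ScanConfig] = None
                           ) -> AnchoredReadSet:
    """Collect abnormal read pairs with >= 1 segment overlapping the region.

    Mates of anchored reads are pulled in even if mapped elsewhere or
    unmapped; concordant fully-aligned pairs are excluded.
    """
    config = config or ScanConfig()
    unmapped = unmapped_store or alignment_store.unmapped
    seen: set[str] = set()
    pairs = []
    for rec in alignment_store.overlapping(region.chrom, region.start,
                                           region.end):
        rid = rec.read_id
        if rid in seen:
            continue
        seen.add(rid)
        frag = alignment_store.by_read[rid]
        if classify_pair(frag, config) == PairClass.CONCORDANT:
            continue
        s1 = alignment_store.read_sequence(rid, 1)
        s2 = alignment_store.read_sequence(rid, 2)
        um = unmapped.reads.get(rid, {})
        s1 = s1 or um.get(1)
        s2 = s2 or um.get(2)
        pairs.append((rid, s1, s2))
    pairs.sort(key=lambda p: p[0])
    return AnchoredReadSet(region=region, pairs=pairs)


# ---------------------------------------------------------------------------
# de Bruijn assembly


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _count_kmers(reads: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            kmer = read[i:i + k]
            if "N" in kmer:
                continue
            c = _canon(kmer)
            counts[c] = counts.get(c, 0) + 1
    return counts


class _Graph:
    """Set-of-kmers view of the de Bruijn graph; nodes are oriented k-mers,
    membership is canonical."""

    def __init__(self, keep: set[str], counts: dict[str, int], k: int):
        self.keep = keep
        self.counts = counts
        self.k = k

    def has(self, kmer: str) -> bool:
        return _canon(kmer) in self.keep

    def successors(self, kmer: str) -> list[str]:
        suf = kmer[1:]
        return [suf + b for b in "ACGT" if self.has(suf + b)]

    def predecessors(self, kmer: str) -> list[str]:
        pre = kmer[:-1]
        return [b + pre for b in "ACGT" if self.has(b + pre)]

    def unitigs(self) -> list[list[str]]:
        """Maximal unbranched oriented k-mer paths, each reported once
        (canonical orientation), deterministically ordered."""
        visited: set[str] = set()
        out = []
        for start in sorted(self.keep):
            if start in visited:
                continue
            path = [start]
            visited.add(start)
            # extend right then left, stopping at branches or visited nodes
            for direction in (1, -1):
                while True:
                    tip = path[-1] if direction == 1 else path[0]
                    nexts = (self.successors(tip) if direction == 1
                             else self.predecessors(tip))
                    if len(nexts) != 1:
                        break
                    nxt = nexts[0]
                    back = (self.predecessors(nxt) if direction == 1
                            else self.successors(nxt))
                    if len(back) != 1:
                        break
                    if _canon(nxt) in visited:
                        break
                    visited.add(_canon(nxt))
                    if direction == 1:
                        path.append(nxt)
                    else:
                        path.insert(0, nxt)
            out.append(path)
        return out

    def path_seq(self, path: list[str]) -> str:
        return path[0] + "".join(p[-1] for p in path[1:])

    def mean_cov(self, path: list[str]) -> float:
        return sum(self.counts[_canon(p)] for p in path) / len(path)


def _clip_tips(g: _Graph, tip_len: int) -> bool:
    """Remove short dead-end unitigs hanging off branch points."""
    removed = False
    for path in g.unitigs():
        seq = g.path_seq(path)
        if len(seq) >= tip_len:
            continue
        first, last = path[0], path[-1]
        left_open = len(g.predecessors(first)) == 0
        right_open = len(g.successors(last)) == 0
        # a tip dangles on exactly one side and competes at the other
        if left_open and not right_open:
            anchor = g.successors(last)
            if anchor and len(g.predecessors(anchor[0])) > 1:
                g.keep -= {_canon(p) for p in path}
                removed = True
        elif right_open and not left_open:
            anchor = g.predecessors(first)
            if anchor and len(g.successors(anchor[0])) > 1:
                g.keep -= {_canon(p) for p in path}
                removed = True
    return removed


def _pop_bubbles(g: _Graph) -> bool:
    """Collapse parallel unitigs sharing both flanking nodes, keeping the
    higher-coverage branch (ties by lexicographic sequence)."""
    arms: dict[tuple, list[list[str]]] = {}
    for path in g.unitigs():
        preds = g.predecessors(path[0])
        succs = g.successors(path[-1])
        if len(preds) == 1 and len(succs) == 1:
            key = (_canon(preds[0]), _canon(succs[0]))
            arms.setdefault(key, []).append(path)
    removed = False
    for key, paths in sorted(arms.items()):
        if len(paths) < 2:
            continue
        paths.sort(key=lambda p: (-g.mean_cov(p), g.path_seq(p)))
        for loser in paths[1:]:
            g.keep -= {_canon(p) for p in loser}
            removed = True
    return removed


def assemble(reads: Iterable[str], k: int = 21, min_kmer_cov: int = 2,
             tip_len: Optional[int] = None,
             region_id: Optional[str] = None) -> list[Contig]:
    """Assemble reads into contigs via a single-k de Bruijn graph.

    k must be odd (palindromic k-mers are unstable under canonicalisation)
    and at least 11.  K-mers seen fewer than ``min_kmer_cov`` times are
    pruned; tips shorter than ``tip_len`` (default 2k) are clipped; every
    maximal unbranched path of length >= k becomes a contig, ordered by read
    support (descending) then sequence.
    """
    if k % 2 == 0 or k < 11:
        raise ValueError("assembler k must be odd and >= 11")
    tip_len = tip_len if tip_len is not None else 2 * k
    reads = [r for r in reads if r]
    if not any(len(r) >= k for r in reads):
        if reads:
            logger.warning("all reads shorter than k=%d; no assembly", k)
        return []
    counts = _count_kmers(reads, k)
    keep = {c for c, n in counts.items() if n >= min_kmer_cov}
    g = _Graph(keep, counts, k)
    for _ in range(10):
        changed = _clip_tips(g, tip_len)
        changed = _pop_bubbles(g) or changed
        if not changed:
            break
    contigs = []
    kmer_to_contig: dict[str, int] = {}
    for idx, path in enumerate(g.unitigs()):
        seq = g.path_seq(path)
        rc = revcomp(seq)
        seq = seq if seq <= rc else rc
        contigs.append([seq, set()])
        for p in path:
            kmer_to_contig[_canon(p)] = idx
    # read support: number of reads contributing >= 1 k-mer to the contig
    for ridx, read in enumerate(reads):
        read = read.upper()
        hit: set[int] = set()
        for i in range(len(read) - k + 1):
            kmer = read[i:i + k]
            if "N" in kmer:
                continue
            cidx = kmer_to_contig.get(_canon(kmer))
            if cidx is not None:
                hit.add(cidx)
        for cidx in hit:
            contigs[cidx][1].add(ridx)
    out = [Contig(seq=seq, k=k, support=len(sup), region_id=region_id)
           for seq, sup in contigs if len(seq) >= k]
    out.sort(key=lambda c: (-c.support, c.seq))
    return out


def assemble_region(anchored: AnchoredReadSet,
                    config: Optional[ScanConfig] = None) -> list[Contig]:
    """Assemble one region's anchored read set with configured parameters."""
    config = config or ScanConfig()
    region = anchored.region
    rid = f"{region.chrom}:{region.start}-{region.end}"
    return assemble(anchored.sequences, k=config.assembly_k,
                    min_kmer_cov=config.min_kmer_cov, region_id=rid)
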