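"""Readers/writers for external formats and the shared coordinate model.

All internal coordinates are 0-based half-open; SAM input (1-based) is
converted at the boundary and all report output is written 1-based again.
Soft- and hard-clipped bases both count toward the clip lengths because the
clipped sequence existed in the read and carries breakpoint geometry.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ScanConfig:
    """Thresholds of the relaxed breakpoint scan and downstream stages.

    t1/t2/t3 are the minimum counts of consistent discordant support for the
    three evidence criteria below chimeric mapping; ``kmer`` is the mapper's
    genome seed size (16 bp or less), used only to bound the minimum unmapped
    part of a partial alignment.
    """

    t1: int = 2
    t2: int = 3
    t3: int = 4
    kmer: int = 15
    max_intron: int = 200_000
    neighbor_window: int = 200
    group_distance: int = 200
    region_halfwidth: int = 250
    # assembly
    assembly_k: int = 21
    min_kmer_cov: int = 2
    # contig re-alignment / chaining
    min_seed: int = 15
    max_overlap: int = 15
    nonunique_frac: float = 0.95
    low_q: float = 0.5
    # support / filtering
    min_span_side: int = 13
    report_gate: int = 2
    min_total: int = 5
    min_ss: float = 1.0
    # legacy v1-style rule: drop junctions with a repetitive fusion-point
    # side unless encompassing pairs corroborate them
    v1_repeat_rescue: bool = False
    # ingestion
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if self.kmer > 16:
            raise ValueError("kmer must be <= 16 (mapper genome seed size)")
        for name in ("t1", "t2", "t3", "kmer", "max_intron", "neighbor_window",
                     "group_distance", "region_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def l_min(self, read_len: int) -> float:
        """Minimum unmapped-part length of a partial alignment: the read-length
        fraction l/5 clamped to [kmer, 1.5*kmer]."""
        return min(max(read_len / 5.0, self.kmer), 1.5 * self.kmer)


# ---------------------------------------------------------------------------
# alignment records


@dataclass
class MateInfo:
    chrom: str
    start: int  # 0-based
    strand: str


@dataclass
class AlignmentRecord:
    """One aligned segment of a read.

    ``clip5``/``clip3`` are clip lengths at the read's 5'/3' end (read
    orientation); ``clip_left``/``clip_right`` give the same clips in
    reference orientation.  ``mate`` is ``None`` for single-end records,
    ``"unmapped"`` if the mate failed to map, else a :class:`MateInfo`.
    """

    read_id: str
    fragment_end: int  # 1 or 2
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    aligned_len: int  # reference-consuming bases
    clip5: int
    clip3: int
    is_supplementary: bool
    segment_group: str
    mate: Optional[object]  # MateInfo | "unmapped" | None
    mapq: int
    read_len: int
    seq: Optional[str] = None  # read-orientation sequence, if available
    cigar: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def clip_left(self) -> int:
        return self.clip5 if self.strand == "+" else self.clip3

    @property
    def clip_right(self) -> int:
        return self.clip3 if self.strand == "+" else self.clip5

    @property
    def is_partial(self) -> bool:
        return self.clip5 > 0 or self.clip3 > 0

    def clipped_seq(self, side: str) -> Optional[str]:
        """Sequence of the clipped part ('left'/'right' in reference
        orientation), when the read sequence is known."""
        if self.seq is None:
            return None
        s = self.seq if self.strand == "+" else revcomp(self.seq)
        if side == "left":
            return s[: self.clip_left] if self.clip_left else ""
        return s[len(s) - self.clip_right:] if self.clip_right else ""


_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _cigar_stats(cigar: str) -> tuple[int, int, int, int, int]:
    """(clip_left, clip_right, ref_len, query_aligned, query_total_incl_hard)."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or sum(int(n) for n, _ in ops) == 0 or \
            "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    lens = [(int(n), o) for n, o in ops]
    clip_l = 0
    i = 0
    while i < len(lens) and lens[i][1] in "SH":
        clip_l += lens[i][0]
        i += 1
    clip_r = 0
    j = len(lens) - 1
    while j >= i and lens[j][1] in "SH":
        clip_r += lens[j][0]
        j -= 1
    ref_len = sum(n for n, o in lens if o in _REF_OPS)
    q_aln = sum(n for n, o in lens if o in "MI=X")
    q_total = sum(n for n, o in lens if o in "MIS=XH")
    return clip_l, clip_r, ref_len, q_aln, q_total


@dataclass
class UnmappedStore:
    """Side channel of reads that did not align: read id -> {end: sequence}."""

    reads: dict = field(default_factory=dict)

    def add(self, read_id: str, end: int, seq: Optional[str]) -> None:
        self.reads.setdefault(read_id, {})[end] = seq or ""

    def __len__(self) -> int:
        return sum(len(v) for v in self.reads.values())


def read_alignments(path, unmapped: Optional[UnmappedStore] = None,
                    min_mapq: int = 0) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    One record per aligned segment; primary and supplementary segments of the
    same read end share a ``segment_group``.  Coordinates are converted from
    1-based SAM to 0-based half-open.  Unmapped reads yield no record but are
    retained in ``unmapped`` for later support counting.  Duplicate alignments
    (identical read id, end, chrom, start, CIGAR) are collapsed.  Malformed
    CIGARs are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: set = set()
    n_bad = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if not af.header.references:
            raise ValueError(f"{path}: header declares no reference sequences")
        for a in af:
            if a.is_secondary:
                continue
            end = 2 if a.is_read2 else 1
            if a.is_unmapped:
                if unmapped is not None:
                    unmapped.add(a.query_name, end, a.query_sequence)
                continue
            if a.reference_name is None:
                raise ValueError(
                    f"{path}: record {a.query_name} references an undeclared "
                    "chromosome")
            if a.mapping_quality < min_mapq:
                continue
            cigar = a.cigarstring or ""
            try:
                clip_l, clip_r, ref_len, _, q_total = _cigar_stats(cigar)
            except ValueError:
                n_bad += 1
                logger.warning("skipping %s: malformed CIGAR %r",
                               a.query_name, cigar)
                continue
            key = (a.query_name, end, a.reference_name, a.reference_start,
                   cigar)
            if key in seen:
                continue
            seen.add(key)
            strand = "-" if a.is_reverse else "+"
            if a.is_paired:
                if a.mate_is_unmapped:
                    mate = "unmapped"
                else:
                    mate = MateInfo(a.next_reference_name,
                                    a.next_reference_start,
                                    "-" if a.mate_is_reverse else "+")
            else:
                mate = None
            seq = a.query_sequence
            if seq and a.is_reverse:
                seq = revcomp(seq)  # store in read orientation
            clip5, clip3 = (clip_l, clip_r) if strand == "+" else (clip_r, clip_l)
            yield AlignmentRecord(
                read_id=a.query_name,
                fragment_end=end,
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_start + ref_len,
                strand=strand,
                aligned_len=ref_len,
                clip5=clip5,
                clip3=clip3,
                is_supplementary=a.is_supplementary,
                segment_group=f"{a.query_name}/{end}",
                mate=mate,
                mapq=a.mapping_quality,
                read_len=q_total,
                seq=seq,
                cigar=cigar,
            )
    if n_bad:
        logger.warning("skipped %d records with malformed CIGARs", n_bad)


class AlignmentStore:
    """In-memory index of alignment records by read id and position."""

    def __init__(self, records: Iterable[AlignmentRecord],
                 unmapped: Optional[UnmappedStore] = None):
        self.records: list[AlignmentRecord] = list(records)
        self.unmapped = unmapped if unmapped is not None else UnmappedStore()
        self.by_read: dict[str, list[AlignmentRecord]] = {}
        self._by_chrom: dict[str, list[AlignmentRecord]] = {}
        for r in self.records:
            self.by_read.setdefault(r.read_id, []).append(r)
            self._by_chrom.setdefault(r.chrom, []).append(r)
        self._starts: dict[str, list[int]] = {}
        for chrom, recs in self._by_chrom.items():
            recs.sort(key=lambda r: r.start)
            self._starts[chrom] = [r.start for r in recs]
        self._max_span = max((r.end - r.start for r in self.records), default=0)

    @classmethod
    def load(cls, path, min_mapq: int = 0) -> "AlignmentStore":
        unmapped = UnmappedStore()
        recs = list(read_alignments(path, unmapped=unmapped, min_mapq=min_mapq))
        return cls(recs, unmapped)

    def overlapping(self, chrom: str, start: int, end: int
                    ) -> list[AlignmentRecord]:
        """Records whose reference span intersects [start, end)."""
        recs = self._by_chrom.get(chrom, [])
        if not recs:
            return []
        lo = bisect.bisect_left(self._starts[chrom], start - self._max_span)
        out = []
        for r in recs[lo:]:
            if r.start >= end:
                break
            if r.end > start:
                out.append(r)
        return out

    def fragment(self, read_id: str) -> dict[int, list[AlignmentRecord]]:
        """All segments of a fragment, grouped by read end."""
        out: dict[int, list[AlignmentRecord]] = {}
        for r in self.by_read.get(read_id, []):
            out.setdefault(r.fragment_end, []).append(r)
        return out

    def read_sequence(self, read_id: str, end: int) -> Optional[str]:
        """Full read-orientation sequence of a read end, if recoverable."""
        best = None
        for r in self.by_read.get(read_id, []):
            if r.fragment_end != end or r.seq is None:
                continue
            if best is None or len(r.seq) > len(best):
                best = r.seq
        if best is None:
            best = self.unmapped.reads.get(read_id, {}).get(end)
        return best


# ---------------------------------------------------------------------------
# gene model


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list  # sorted [start, end) 0-based
    cds: list = field(default_factory=list)  # sorted [start, end)

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.id}")

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def tx_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _fwd_only(self) -> None:
        if self.strand != "+":
            raise NotImplementedError(
                "transcript-coordinate projection implemented for forward-"
                "strand transcripts only")

    def tx_offset(self, pos: int) -> Optional[int]:
        """Transcript-coordinate offset of a genomic position inside an
        exon; None for intronic/outside positions."""
        self._fwd_only()
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + pos - s
            off += e - s
        return None

    def tx_pos(self, offset: int) -> int:
        """Genomic position of transcript-coordinate ``offset``."""
        self._fwd_only()
        for s, e in self.exons:
            if offset < e - s:
                return s + offset
            offset -= e - s
        raise IndexError("offset beyond transcript length")

    def coding_pos(self, offset: int) -> int:
        """Genomic position of coding-coordinate ``offset`` (inverse of
        :meth:`coding_offset`)."""
        self._fwd_only()
        for s, e in self.cds:
            if offset < e - s:
                return s + offset
            offset -= e - s
        raise IndexError("offset beyond CDS length")

    def project(self, ts: int, te: int) -> list[tuple[int, int]]:
        """Genomic blocks [(gstart, gend), ...] covered by the transcript
        interval [ts, te)."""
        self._fwd_only()
        if not 0 <= ts < te <= self.tx_len:
            raise ValueError("interval outside transcript")
        blocks = []
        off = 0
        for s, e in self.exons:
            lo = max(ts, off)
            hi = min(te, off + e - s)
            if hi > lo:
                blocks.append((s + lo - off, s + hi - off))
            off += e - s
        return blocks

    def spliced_seq(self, genome: dict) -> str:
        """Exon-concatenated transcript sequence (forward strand)."""
        self._fwd_only()
        chrom_seq = genome[self.chrom]
        return "".join(str(chrom_seq[s:e]) for s, e in self.exons)

    def coding_offset(self, pos: int) -> Optional[int]:
        """0-based coding offset (from the CDS start, in transcript
        orientation) of a genomic position inside the CDS; None outside."""
        if not self.cds:
            return None
        blocks = self.cds if self.strand == "+" else self.cds[::-1]
        off = 0
        for s, e in blocks:
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
            off += e - s
        return None


@dataclass
class Gene:
    id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict = field(default_factory=dict)

    def longest_cds_transcript(self) -> Optional[Transcript]:
        coding = [t for t in self.transcripts.values() if t.cds]
        if not coding:
            return None
        return max(coding, key=lambda t: (t.cds_len, t.id))


class GeneModel:
    """Interval-indexed gene annotation supporting point/interval queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {g.id: g for g in genes}
        if not self.genes:
            raise ValueError("gene model contains zero genes")
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for gl in self._by_chrom.values():
            gl.sort(key=lambda g: g.start)

    def query(self, chrom: str, pos: int) -> list[Gene]:
        return self.query_interval(chrom, pos, pos + 1)

    def query_interval(self, chrom: str, start: int, end: int) -> list[Gene]:
        return [g for g in self._by_chrom.get(chrom, [])
                if g.start < end and g.end > start]


def _parse_gtf(path: Path) -> GeneModel:
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique",
                                disable_infer_genes=True,
                                disable_infer_transcripts=True)
    except gffutils.exceptions.EmptyInputError:
        raise ValueError(f"{path}: gene model contains zero genes") from None
    tx_meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        tid = feat.attributes.get("transcript_id", [None])[0]
        if not gid:
            continue
        if not tid:
            logger.warning("%s feature without transcript_id; attaching to "
                           "synthetic transcript of gene %s",
                           feat.featuretype, gid)
            tid = f"{gid}.synthetic"
        meta = tx_meta.setdefault(tid, {
            "gene_id": gid,
            "gene_name": feat.attributes.get("gene_name", [gid])[0],
            "chrom": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": []})
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            meta["exons"].append(iv)
        else:
            meta["cds"].append(iv)
    return _build_model(tx_meta)


def _parse_bed12(path: Path) -> GeneModel:
    tx_meta: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: expected BED12, got {len(f)} cols")
            chrom, start, end, name, _score, strand = f[:6]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            start = int(start)
            exons = [(start + o, start + o + sz)
                     for o, sz in zip(offsets, sizes)]
            cds = []
            if thick_e > thick_s:
                for s, e in exons:
                    cs, ce = max(s, thick_s), min(e, thick_e)
                    if ce > cs:
                        cds.append((cs, ce))
            # gene id convention: transcript names "GENE.tN" group under GENE
            gid = re.sub(r"\.t\d+$", "", name)
            tx_meta[name] = {"gene_id": gid, "gene_name": gid, "chrom": chrom,
                             "strand": strand, "exons": exons, "cds": cds}
    return _build_model(tx_meta)


def _build_model(tx_meta: dict) -> GeneModel:
    genes: dict[str, Gene] = {}
    for tid, m in sorted(tx_meta.items()):
        exons = m["exons"] or m["cds"]
        if not exons:
            continue
        tx = Transcript(id=tid, gene_id=m["gene_id"], chrom=m["chrom"],
                        strand=m["strand"], exons=exons, cds=m["cds"])
        g = genes.get(m["gene_id"])
        if g is None:
            g = Gene(id=m["gene_id"], name=m["gene_name"], chrom=m["chrom"],
                     strand=m["strand"], start=tx.exons[0][0],
                     end=tx.exons[-1][1])
            genes[m["gene_id"]] = g
        g.start = min(g.start, tx.exons[0][0])
        g.end = max(g.end, tx.exons[-1][1])
        g.transcripts[tid] = tx
    return GeneModel(genes.values())


def load_gene_model(path) -> GeneModel:
    """Load a gene model from GTF or BED12 (auto-detected)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".bed", ".bed12"):
        return _parse_bed12(path)
    return _parse_gtf(path)


# ---------------------------------------------------------------------------
# interval sets (repeats, self-chain)


class IntervalSet:
    """Merged, sorted genomic intervals with point membership queries."""

    def __init__(self, intervals: Iterable[tuple] = (), label: str = ""):
        self.label = label
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end < 0:
                raise ValueError("negative coordinates in interval set")
            if end > start:
                by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[chrom] = [(s, e) for s, e in merged]
        self._starts = {c: [s for s, _ in ivs]
                        for c, ivs in self._merged.items()}

    def __contains__(self, item: tuple) -> bool:
        chrom, pos = item
        return self.query(chrom, pos)

    def query(self, chrom: str, pos: int) -> bool:
        ivs = self._merged.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._merged.get(chrom, []))


def load_interval_set(path, label: str = "") -> IntervalSet:
    """Load a BED (3+ columns, 0-based half-open) into an IntervalSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ivs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                f = line.split()
            ivs.append((f[0], int(f[1]), int(f[2])))
    return IntervalSet(ivs, label=label)


# ---------------------------------------------------------------------------
# report writing

REPORT_COLUMNS = [
    "rank", "gene5", "gene3", "chrom5", "breakpoint5", "strand5",
    "chrom3", "breakpoint3", "strand3", "spanning", "encompassing", "total",
    "SS", "Q", "type", "frame", "flags", "isoform_breakpoints",
    "contig_sequence",
]


def write_report(candidates, path, config: Optional[ScanConfig] = None) -> None:
    """Write ranked fusion candidates as TSV; breakpoints are 1-based."""
    lines = []
    if config is not None:
        for key in ("t1", "t2", "t3", "min_span_side", "report_gate",
                    "min_total", "min_ss", "group_distance",
                    "region_halfwidth", "max_overlap"):
            lines.append(f"# {key}={getattr(config, key)}")
    lines.append("\t".join(REPORT_COLUMNS))
    for rank, c in enumerate(candidates, start=1):
        j = c.junction
        iso = ";".join(
            f"{b5.chrom}:{b5.pos + 1}|{b3.chrom}:{b3.pos + 1}"
            for b5, b3 in getattr(c, "isoform_breakpoints", [])) or "."
        row = [
            rank, j.gene5, j.gene3,
            j.break5.chrom, j.break5.pos + 1, j.break5.strand,
            j.break3.chrom, j.break3.pos + 1, j.break3.strand,
            c.spanning.n, c.encompassing, c.total,
            f"{c.ss:.4f}", f"{c.q:.4f}", c.type, c.frame,
            ",".join(sorted(j.flags)) or ".",
            iso, j.contig.seq,
        ]
        lines.append("\t".join(str(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
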