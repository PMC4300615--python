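"""Relaxed detection of candidate regions containing fusion breakpoints.

A potential breakpoint is called from a read X when it satisfies one of four
criteria, in decreasing strength of evidence:

1. X shows chimeric mapping (segments on two chromosomes/strands, or further
   apart than the maximum allowed intron length).
2. X is partially aligned with a discordant mate, the unmapped part is at
   least ``l_min`` nt (read length / 5, clamped to [kmer, 1.5*kmer]) with no
   undecided nucleotides, and at least t1 other discordant alignments within
   the ±200 bp neighbourhood are consistent with X.
3. As (2) but with a shorter unmapped part, requiring t2 consistent
   discordant alignments.
4. A group of at least t3 entirely aligned discordant pairs, all consistent
   with one fusion point; the call is placed where the reads' 3' ends extend
   farthest.

Calls are then grouped within 200 bp (after removing calls in repetitive
regions); each group yields a ±250 bp candidate region.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_model import (AlignmentRecord, AlignmentStore, IntervalSet,
                       MateInfo, ScanConfig)

LEFT_ANCHORED = "left-anchored"    # known sequence lies left of pos
RIGHT_ANCHORED = "right-anchored"  # known sequence lies right of pos


class PairClass(enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    PARTIAL = "partial"
    CHIMERIC = "chimeric"
    UNMAPPED_MATE = "unmapped-mate"


@dataclass
class BreakpointCall:
    chrom: str
    pos: int  # 0-based
    orientation: str  # LEFT_ANCHORED or RIGHT_ANCHORED
    tier: int  # 1..4, strongest criterion satisfied
    partner_hint: Optional[tuple] = None  # (chrom, approx pos, strand)
    support_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3, 4):
            raise ValueError("tier must be in 1..4")


@dataclass
class CallGroup:
    chrom: str
    representative: BreakpointCall
    members: list = field(default_factory=list)


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    representative: BreakpointCall
    member_calls: list = field(default_factory=list)

    @property
    def window(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# record-level helpers


def record_is_discordant(rec: AlignmentRecord, config: ScanConfig) -> bool:
    """True if the record's pair is aberrant: mates on different chromosomes,
    the same strand orientation, or farther apart than the max intron."""
    m = rec.mate
    if not isinstance(m, MateInfo):
        return False
    return (m.chrom != rec.chrom or m.strand == rec.strand
            or abs(m.start - rec.start) > config.max_intron)


def read_is_chimeric(segments: list[AlignmentRecord],
                     config: ScanConfig) -> bool:
    """True if one read's segments span chromosomes/strands or a distance
    longer than the maximum allowed intron length."""
    if len(segments) < 2:
        return False
    for i, a in enumerate(segments):
        for b in segments[i + 1:]:
            if (a.chrom != b.chrom or a.strand != b.strand
                    or abs(a.start - b.start) > config.max_intron):
                return True
    return False


def classify_pair(records: list[AlignmentRecord],
                  config: ScanConfig) -> PairClass:
    """Classify one fragment's alignment records.

    Chimeric and partial take precedence (they identify the read carrying the
    junction); a chimeric read, when its segments are viewed as a split pair,
    is also discordant by construction.
    """
    ids = {r.read_id for r in records}
    if len(ids) != 1:
        raise ValueError("records of classify_pair must share one read id")
    ends = sorted({r.fragment_end for r in records})
    if any(e not in (1, 2) for e in ends):
        raise ValueError(f"corrupt fragment: read ends {ends}")
    by_end = {e: [r for r in records if r.fragment_end == e] for e in ends}
    if any(read_is_chimeric(segs, config) for segs in by_end.values()):
        return PairClass.CHIMERIC
    for segs in by_end.values():
        for r in segs:
            if r.is_partial and not r.is_supplementary and len(segs) == 1:
                return PairClass.PARTIAL
    if any(record_is_discordant(r, config) for r in records):
        return PairClass.DISCORDANT
    if any(r.mate == "unmapped" for r in records):
        return PairClass.UNMAPPED_MATE
    return PairClass.CONCORDANT


# ---------------------------------------------------------------------------
# breakpoint calling


def _clip_breakpoint(rec: AlignmentRecord) -> tuple[int, str, int]:
    """(pos, orientation, unmapped_len) at the larger clipped side."""
    if rec.clip_right >= rec.clip_left:
        return rec.end, LEFT_ANCHORED, rec.clip_right
    return rec.start, RIGHT_ANCHORED, rec.clip_left


def _partner_side(rec: AlignmentRecord) -> Optional[tuple[str, str]]:
    """(chrom, strand) the mate implies for the other fusion side."""
    if isinstance(rec.mate, MateInfo):
        return (rec.mate.chrom, rec.mate.strand)
    return None


def _consistent_neighbors(x_rec: AlignmentRecord, x_pos: int,
                          partner: tuple[str, str],
                          store: AlignmentStore,
                          config: ScanConfig) -> set[str]:
    """Read ids of other discordant alignments consistent with read X:
    anchored within the neighbour window of X's breakpoint and implying the
    same (chromosome, strand) for the partner side."""
    w = config.neighbor_window
    out: set[str] = set()
    for r in store.overlapping(x_rec.chrom, x_pos - w, x_pos + w + 1):
        if r.read_id == x_rec.read_id:
            continue
        if not record_is_discordant(r, config):
            continue
        if _partner_side(r) != partner:
            continue
        out.add(r.read_id)
    return out


def _clip_is_clean(rec: AlignmentRecord) -> bool:
    """No undecided nucleotides in the clipped part (unknown seq passes)."""
    side = "right" if rec.clip_right >= rec.clip_left else "left"
    clipped = rec.clipped_seq(side)
    return clipped is None or "N" not in clipped.upper()


def call_breakpoints(records, config: ScanConfig) -> list[BreakpointCall]:
    """Emit one breakpoint call per read satisfying the strongest of the four
    evidence criteria, plus one call per group of entirely aligned discordant
    pairs meeting the t3 rule."""
    store = records if isinstance(records, AlignmentStore) \
        else AlignmentStore(records)
    calls: list[BreakpointCall] = []

    groups: dict[str, list[AlignmentRecord]] = {}
    for r in store.records:
        groups.setdefault(r.segment_group, []).append(r)

    tier4_pool: list[AlignmentRecord] = []
    for _sg, segs in sorted(groups.items()):
        segs.sort(key=lambda r: (r.is_supplementary, r.chrom, r.start))
        x = segs[0]  # primary segment
        if read_is_chimeric(segs, config):
            pos, orient, _ = _clip_breakpoint(x)
            other = segs[1] if len(segs) > 1 else None
            hint = (other.chrom, other.start, other.strand) if other else None
            calls.append(BreakpointCall(
                chrom=x.chrom, pos=pos, orientation=orient, tier=1,
                partner_hint=hint, support_ids=frozenset([x.read_id])))
            continue
        if x.is_partial and len(segs) == 1:
            partner = _partner_side(x)
            if partner is None or not record_is_discordant(x, config):
                continue
            pos, orient, unmapped = _clip_breakpoint(x)
            neighbors = _consistent_neighbors(x, pos, partner, store, config)
            long_clip = (unmapped >= config.l_min(x.read_len)
                         and _clip_is_clean(x))
            tier = None
            if long_clip and len(neighbors) >= config.t1:
                tier = 2
            elif len(neighbors) >= config.t2:
                tier = 3
            if tier is not None:
                calls.append(BreakpointCall(
                    chrom=x.chrom, pos=pos, orientation=orient, tier=tier,
                    partner_hint=(partner[0], x.mate.start, partner[1]),
                    support_ids=frozenset([x.read_id]) | frozenset(neighbors)))
            continue
        if not x.is_partial and len(segs) == 1 \
                and record_is_discordant(x, config):
            tier4_pool.append(x)

    calls.extend(_tier4_calls(tier4_pool, config))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.tier))
    return calls


def _tier4_calls(pool: list[AlignmentRecord],
                 config: ScanConfig) -> list[BreakpointCall]:
    """Criterion (4): groups of >= t3 entirely aligned discordant pairs, all
    consistent with one fusion point.  Grouped per fusion side by the ordered
    (chromosome, strand, mate chromosome, mate strand) signature; mixed
    groups are split by partner before counting.  The call sits where the
    reads' 3' ends extend farthest on this side."""
    by_sig: dict[tuple, list[AlignmentRecord]] = {}
    for r in pool:
        sig = (r.chrom, r.strand) + _partner_side(r)
        by_sig.setdefault(sig, []).append(r)
    calls = []
    for sig, recs in sorted(by_sig.items()):
        recs.sort(key=lambda r: r.start)
        # single-linkage clustering of anchors within the neighbour window
        cluster: list[AlignmentRecord] = []
        clusters: list[list[AlignmentRecord]] = []
        for r in recs:
            if cluster and r.start - cluster[-1].start > config.neighbor_window:
                clusters.append(cluster)
                cluster = []
            cluster.append(r)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            frag_ids = {r.read_id for r in cl}
            if len(frag_ids) < config.t3:
                continue
            chrom, strand, mchrom, mstrand = sig
            if strand == "+":
                pos, orient = max(r.end for r in cl), LEFT_ANCHORED
            else:
                pos, orient = min(r.start for r in cl), RIGHT_ANCHORED
            mate_pos = min(r.mate.start for r in cl) if mstrand == "-" \
                else max(r.mate.start for r in cl)
            calls.append(BreakpointCall(
                chrom=chrom, pos=pos, orientation=orient, tier=4,
                partner_hint=(mchrom, mate_pos, mstrand),
                support_ids=frozenset(frag_ids)))
    return calls


# ---------------------------------------------------------------------------
# grouping and regions


def merge_calls(calls: Iterable[BreakpointCall],
                repeat_set: Optional[IntervalSet],
                config: ScanConfig) -> list[CallGroup]:
    """Group breakpoint calls within ``group_distance`` (single linkage) after
    removing calls from repetitive regions; the call with the strongest
    evidence (lowest tier, then most support, then smallest position)
    represents the group."""
    kept = [c for c in calls
            if repeat_set is None or not repeat_set.query(c.chrom, c.pos)]
    by_chrom: dict[str, list[BreakpointCall]] = {}
    for c in kept:
        by_chrom.setdefault(c.chrom, []).append(c)
    groups = []
    for chrom, cl in sorted(by_chrom.items()):
        cl.sort(key=lambda c: c.pos)
        bucket: list[BreakpointCall] = []
        for c in cl:
            if bucket and c.pos - bucket[-1].pos > config.group_distance:
                groups.append(_close_group(chrom, bucket))
                bucket = []
            bucket.append(c)
        if bucket:
            groups.append(_close_group(chrom, bucket))
    return groups


def _close_group(chrom: str, members: list[BreakpointCall]) -> CallGroup:
    rep = min(members, key=lambda c: (c.tier, -len(c.support_ids), c.pos))
    return CallGroup(chrom=chrom, representative=rep, members=list(members))


def candidate_regions(groups: Iterable[CallGroup],
                      genome_lengths: dict[str, int],
                      config: ScanConfig) -> list[CandidateRegion]:
    """One ±250 bp window per group, clipped at chromosome bounds; windows
    are not merged even when they overlap."""
    regions = []
    hw = config.region_halfwidth
    for g in groups:
        pos = g.representative.pos
        chrom_len = genome_lengths.get(g.chrom)
        start = max(0, pos - hw)
        end = pos + hw
        if chrom_len is not None:
            end = min(end, chrom_len)
        regions.append(CandidateRegion(
            chrom=g.chrom, start=start, end=end,
            representative=g.representative, member_calls=list(g.members)))
    return regions
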