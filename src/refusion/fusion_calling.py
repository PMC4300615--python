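"""Support quantification, scoring, filtering and ranking of fusion calls.

A read pair that is improperly aligned (discordant, partial, chimeric, or
initially unmapped) supports a putative junction either directly — one end
spans the fusion point with at least 13 nt aligned on both sides — or
indirectly, by encompassing the fusion point with its two mates on opposite
sides.  Support is counted non-redundantly.  Candidates are scored with the
Spanning Score

    SS = N - sum_i |L_i - R_i| / (L_i + R_i)

over the N independent spanning reads with left/right aligned lengths L_i,
R_i; ranked by SS, then encompassing count, then alignment score Q; and
filtered: fewer than 5 total supporting reads, SS below 1, or both
breakpoints in repeat/self-chain regions remove a candidate.  Isoform
junctions of the same oriented gene pair are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_model import GeneModel, ScanConfig, revcomp
from .junction_discovery import JunctionCandidate


@dataclass
class SpanningEvidence:
    """Per-read left/right aligned lengths around the fusion point."""

    entries: list = field(default_factory=list)  # (read_id, L, R)

    @property
    def n(self) -> int:
        return len(self.entries)

    def add(self, read_id: str, left: int, right: int) -> None:
        if left < 1 or right < 1:
            raise ValueError("spanning sides must be positive")
        self.entries.append((read_id, left, right))


@dataclass
class FusionCandidate:
    junction: JunctionCandidate
    spanning: SpanningEvidence
    encompassing: int
    ss: float = 0.0
    type: str = "NA"  # Intra / Inter
    frame: str = "NA"  # IF / OF / NA
    isoform_breakpoints: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.spanning.n + self.encompassing

    @property
    def q(self) -> float:
        return self.junction.Q

    @property
    def isoform_group(self) -> tuple:
        return (self.junction.gene5, self.junction.gene3)


# ---------------------------------------------------------------------------
# read-to-contig alignment for support counting


def _best_offset(read: str, contig: str, seed: int = 13,
                 min_identity: float = 0.9) -> Optional[tuple[int, int, int]]:
    """Best ungapped placement of ``read`` on ``contig`` (one orientation).

    Returns (start, end, matches) of the aligned overlap on the contig, or
    None if no placement reaches ``min_identity`` over >= seed bases.
    """
    offsets: set[int] = set()
    step = max(1, seed // 2)
    for p in range(0, max(1, len(read) - seed + 1), step):
        mer = read[p:p + seed]
        pos = contig.find(mer)
        while pos != -1:
            offsets.add(pos - p)
            pos = contig.find(mer, pos + 1)
    best = None
    for off in sorted(offsets):
        s = max(0, off)
        e = min(len(contig), off + len(read))
        if e - s < seed:
            continue
        matches = sum(1 for i in range(s, e) if contig[i] == read[i - off])
        if matches < min_identity * (e - s):
            continue
        if best is None or matches > best[2]:
            best = (s, e, matches)
    return best


def align_pair_to_contig(seq1: Optional[str], seq2: Optional[str],
                         contig: str) -> list[Optional[tuple[int, int]]]:
    """Place each mate on the contig in its best orientation; the pair is
    expected to face inward so both orientation combinations are tried."""
    placements: list[Optional[tuple[int, int]]] = []
    for seq in (seq1, seq2):
        if not seq:
            placements.append(None)
            continue
        cands = [_best_offset(s, contig) for s in (seq, revcomp(seq))]
        cands = [c for c in cands if c is not None]
        if not cands:
            placements.append(None)
            continue
        s, e, _m = max(cands, key=lambda c: c[2])
        placements.append((s, e))
    return placements


def collect_support(junction: JunctionCandidate,
                    read_pairs: Iterable[tuple],
                    config: Optional[ScanConfig] = None
                    ) -> tuple[SpanningEvidence, int]:
    """Count spanning and encompassing support for a junction.

    ``read_pairs`` yields (read_id, seq1, seq2) of improperly aligned pairs
    (including initially unmapped mates).  A read spanning the fusion point
    needs >= 13 nt aligned on both sides; otherwise a pair whose mates sit on
    opposite sides without crossing encompasses the junction.  Reads with
    identical (junction offset, mate offset) collapse to one unit; a read
    contributes to at most one category.
    """
    config = config or ScanConfig()
    contig = junction.contig.seq
    b = junction.contig_break
    min_side = config.min_span_side
    spanning = SpanningEvidence()
    seen_span: set[tuple] = set()
    seen_enc: set[tuple] = set()
    n_enc = 0
    for read_id, seq1, seq2 in read_pairs:
        p1, p2 = align_pair_to_contig(seq1, seq2, contig)
        span_placement = mate_placement = None
        for p, other in ((p1, p2), (p2, p1)):
            if p is None:
                continue
            left, right = b - p[0], p[1] - b
            if left >= min_side and right >= min_side:
                span_placement, mate_placement = p, other
                break
        if span_placement is not None:
            key = (span_placement[0],
                   mate_placement[0] if mate_placement else None)
            if key in seen_span:
                continue
            seen_span.add(key)
            spanning.add(read_id, b - span_placement[0],
                         span_placement[1] - b)
            continue
        if p1 is None or p2 is None:
            continue
        sides = []
        for s, e in (p1, p2):
            sides.append("L" if (b - s) > (e - b) else "R")
        if sides[0] != sides[1]:
            key = (min(p1[0], p2[0]), max(p1[0], p2[0]))
            if key in seen_enc:
                continue
            seen_enc.add(key)
            n_enc += 1
    return spanning, n_enc


# ---------------------------------------------------------------------------
# scoring, gating, ranking


def spanning_score(evidence: SpanningEvidence) -> float:
    """SS = N - sum |L-R|/(L+R); 0 when there are no spanning reads."""
    return evidence.n - sum(abs(l - r) / (l + r)
                            for _id, l, r in evidence.entries)


def report_gate(candidate: FusionCandidate,
                config: Optional[ScanConfig] = None) -> bool:
    """Junctions need at least two non-redundant supporting reads."""
    config = config or ScanConfig()
    return candidate.total >= config.report_gate


def rank_candidates(candidates: list[FusionCandidate]
                    ) -> list[FusionCandidate]:
    """Order by Spanning Score, then encompassing pairs, then Q, applied in
    that order; residual ties by gene pair for determinism."""
    return sorted(candidates,
                  key=lambda c: (-c.ss, -c.encompassing, -c.q,
                                 c.junction.gene5, c.junction.gene3))


def _side_flagged(flags: set, side: str) -> bool:
    return any(f.endswith(side) and f != "low_Q" for f in flags
               if f[:-1] in ("repeat", "selfchain"))


def final_filter(candidates: list[FusionCandidate],
                 config: Optional[ScanConfig] = None
                 ) -> list[FusionCandidate]:
    """Drop predictions with fewer than 5 total supporting reads, spanning
    score below 1, or both breakpoints in repeat/self-chain regions.

    With ``v1_repeat_rescue`` the stricter legacy rule also applies: any
    repetitive fusion-point side removes the candidate unless encompassing
    pairs independently corroborate it.
    """
    config = config or ScanConfig()
    out = []
    for c in candidates:
        if c.total < config.min_total:
            continue
        if c.ss < config.min_ss:
            continue
        if _side_flagged(c.junction.flags, "5") \
                and _side_flagged(c.junction.flags, "3"):
            continue
        if config.v1_repeat_rescue and c.encompassing == 0 \
                and (_side_flagged(c.junction.flags, "5")
                     or _side_flagged(c.junction.flags, "3")):
            continue
        out.append(c)
    return out


def merge_isoforms(candidates: list[FusionCandidate]
                   ) -> list[FusionCandidate]:
    """Collapse candidates sharing the oriented (gene5, gene3) pair to the
    best-ranked junction; all isoform breakpoints are retained on the
    representative.  Swapped 5'/3' orientations are distinct fusions."""
    merged: dict[tuple, FusionCandidate] = {}
    order: list[tuple] = []
    for c in candidates:  # candidates arrive ranked
        key = c.isoform_group
        if key not in merged:
            merged[key] = c
            order.append(key)
            c.isoform_breakpoints = [(c.junction.break5, c.junction.break3)]
        else:
            merged[key].isoform_breakpoints.append(
                (c.junction.break5, c.junction.break3))
    return [merged[k] for k in order]


# ---------------------------------------------------------------------------
# classification


def classify_candidate(candidate: FusionCandidate, gene_model: GeneModel
                       ) -> tuple[str, str]:
    """(type, frame): Intra iff both breakpoints share a chromosome; IF iff
    the fused coding sequences stay in one reading frame across the junction,
    judged on the longest-CDS transcript of each partner; NA when either
    breakpoint falls outside an annotated CDS."""
    j = candidate.junction
    ftype = "Intra" if j.break5.chrom == j.break3.chrom else "Inter"
    g5 = gene_model.genes.get(j.gene5)
    g3 = gene_model.genes.get(j.gene3)
    frame = "NA"
    t5 = g5.longest_cds_transcript() if g5 else None
    t3 = g3.longest_cds_transcript() if g3 else None
    if t5 is not None and t3 is not None:
        off5 = t5.coding_offset(j.break5.pos)
        off3 = t3.coding_offset(j.break3.pos)
        if off5 is not None and off3 is not None:
            retained5 = off5 + 1  # breakpoint base is the last retained
            skipped3 = off3       # breakpoint base is the first retained
            frame = "IF" if (retained5 - skipped3) % 3 == 0 else "OF"
    return ftype, frame


def finalize_candidates(raw: list[FusionCandidate], gene_model: GeneModel,
                        config: Optional[ScanConfig] = None
                        ) -> list[FusionCandidate]:
    """Gate, rank, filter, merge and classify candidates for reporting."""
    config = config or ScanConfig()
    for c in raw:
        c.ss = spanning_score(c.spanning)
    gated = [c for c in raw if report_gate(c, config)]
    ranked = rank_candidates(gated)
    filtered = final_filter(ranked, config)
    merged = merge_isoforms(filtered)
    for c in merged:
        c.type, c.frame = classify_candidate(c, gene_model)
    return merged
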