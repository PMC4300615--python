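"""Relaxed breakpoint detection: the four evidence criteria, grouping and
candidate regions, checked against a literal criterion-by-criterion oracle.
"""

from collections import Counter

import pytest

from conftest import make_record, mate_at
from refusion.breakpoint_scan import (LEFT_ANCHORED, PairClass,
                                      call_breakpoints, candidate_regions,
                                      classify_pair, merge_calls)
from refusion.io_model import AlignmentStore, IntervalSet, MateInfo, ScanConfig


# ---------------------------------------------------------------------------
# naive oracle: each criterion applied literally, O(n^2)


def _is_discordant(r, cfg):
    m = r.mate
    return isinstance(m, MateInfo) and (
        m.chrom != r.chrom or m.strand == r.strand
        or abs(m.start - r.start) > cfg.max_intron)


def _clip_side(rec):
    if rec.clip_right >= rec.clip_left:
        return rec.end, "left-anchored", rec.clip_right
    return rec.start, "right-anchored", rec.clip_left


def naive_call_breakpoints(records, cfg):
    """Literal re-statement of the four criteria; no indexing, no sharing
    with the implementation under test."""
    groups = {}
    for r in records:
        groups.setdefault((r.read_id, r.fragment_end), []).append(r)
    calls = []
    tier4_pool = []
    for key in sorted(groups):
        segs = sorted(groups[key],
                      key=lambda r: (r.is_supplementary, r.chrom, r.start))
        x = segs[0]
        chimeric = any(
            a.chrom != b.chrom or a.strand != b.strand
            or abs(a.start - b.start) > cfg.max_intron
            for i, a in enumerate(segs) for b in segs[i + 1:])
        if chimeric:
            pos, orient, _ = _clip_side(x)
            calls.append((x.chrom, pos, orient, 1, frozenset([x.read_id])))
            continue
        if len(segs) == 1 and (x.clip5 or x.clip3):
            if not _is_discordant(x, cfg):
                continue
            pos, orient, unmapped = _clip_side(x)
            neigh = set()
            for r in records:
                if r.read_id == x.read_id or not _is_discordant(r, cfg):
                    continue
                if r.chrom != x.chrom:
                    continue
                if not (r.start < pos + cfg.neighbor_window + 1
                        and r.end > pos - cfg.neighbor_window):
                    continue
                if (r.mate.chrom, r.mate.strand) != (x.mate.chrom,
                                                     x.mate.strand):
                    continue
                neigh.add(r.read_id)
            side = "right" if x.clip_right >= x.clip_left else "left"
            clipped = x.clipped_seq(side)
            clean = clipped is None or "N" not in clipped.upper()
            long_enough = unmapped >= cfg.l_min(x.read_len) and clean
            if long_enough and len(neigh) >= cfg.t1:
                tier = 2
            elif len(neigh) >= cfg.t2:
                tier = 3
            else:
                continue
            calls.append((x.chrom, pos, orient, tier,
                          frozenset([x.read_id]) | frozenset(neigh)))
            continue
        if len(segs) == 1 and not (x.clip5 or x.clip3) \
                and _is_discordant(x, cfg):
            tier4_pool.append(x)
    # criterion (4) via union-find over same-signature records
    by_sig = {}
    for r in tier4_pool:
        sig = (r.chrom, r.strand, r.mate.chrom, r.mate.strand)
        by_sig.setdefault(sig, []).append(r)
    for sig, recs in sorted(by_sig.items()):
        parent = list(range(len(recs)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, a in enumerate(recs):
            for j, b in enumerate(recs):
                if i < j and abs(a.start - b.start) <= cfg.neighbor_window:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(len(recs)):
            clusters.setdefault(find(i), []).append(recs[i])
        for cl in clusters.values():
            ids = {r.read_id for r in cl}
            if len(ids) < cfg.t3:
                continue
            chrom, strand, mchrom, mstrand = sig
            if strand == "+":
                pos, orient = max(r.end for r in cl), "left-anchored"
            else:
                pos, orient = min(r.start for r in cl), "right-anchored"
            calls.append((chrom, pos, orient, 4, frozenset(ids)))
    return calls


def _as_tuples(calls):
    return Counter((c.chrom, c.pos, c.orientation, c.tier, c.support_ids)
                   for c in calls)


def random_record_set(rng, max_frags=20):
    records = []
    n = int(rng.integers(1, max_frags + 1))
    for i in range(n):
        rid = f"f{i}"
        kind = int(rng.integers(0, 5))
        chrom = f"chr{int(rng.integers(1, 3))}"
        pos = int(rng.integers(0, 3000))
        if kind == 0:  # concordant pair
            records.append(make_record(rid, 1, chrom, pos,
                                       mate=mate_at(chrom, pos + 200, "-")))
            records.append(make_record(rid, 2, chrom, pos + 200, strand="-",
                                       mate=mate_at(chrom, pos, "+")))
        elif kind == 1:  # fully aligned discordant pair
            ochrom = f"chr{int(rng.integers(1, 3))}"
            opos = int(rng.integers(0, 3000))
            records.append(make_record(rid, 1, chrom, pos,
                                       mate=mate_at(ochrom, opos, "-")))
            records.append(make_record(rid, 2, ochrom, opos, strand="-",
                                       mate=mate_at(chrom, pos, "+")))
        elif kind == 2:  # partial read, mate possibly discordant
            clip = int(rng.integers(5, 45))
            mchrom = f"chr{int(rng.integers(1, 3))}"
            records.append(make_record(
                rid, 1, chrom, pos, aligned=100 - clip, clip3=clip,
                read_len=100, mate=mate_at(mchrom, int(rng.integers(0, 3000)),
                                           "-")))
        elif kind == 3:  # chimeric read
            records.append(make_record(rid, 1, chrom, pos, aligned=50,
                                       clip3=50, read_len=100,
                                       mate=mate_at(chrom, pos + 150, "-")))
            records.append(make_record(rid, 1, "chr2",
                                       int(rng.integers(0, 3000)), aligned=50,
                                       clip5=50, read_len=100,
                                       supplementary=True,
                                       mate=mate_at(chrom, pos + 150, "-")))
        else:  # unmapped mate
            records.append(make_record(rid, 1, chrom, pos, mate="unmapped"))
    return records


class TestOracleEquivalence:
    def test_random_sets_match_naive(self, rng, config):
        for _ in range(60):
            records = random_record_set(rng)
            got = _as_tuples(call_breakpoints(AlignmentStore(records),
                                              config))
            want = Counter(naive_call_breakpoints(records, config))
            assert got == want

    def test_threshold_monotonicity(self, rng):
        for _ in range(20):
            records = random_record_set(rng)
            loose = call_breakpoints(
                AlignmentStore(records), ScanConfig(t1=1, t2=1, t3=1))
            default = call_breakpoints(AlignmentStore(records), ScanConfig())
            strict = call_breakpoints(
                AlignmentStore(records), ScanConfig(t1=5, t2=6, t3=8))
            keys = lambda cs: {(c.chrom, c.pos, c.tier) for c in cs}
            assert keys(strict) <= keys(default) <= keys(loose)


class TestClassifyPair:
    def test_concordant_fr_pair(self, config):
        recs = [make_record("r", 1, "chr1", 1000,
                            mate=mate_at("chr1", 1300, "-")),
                make_record("r", 2, "chr1", 1300, strand="-",
                            mate=mate_at("chr1", 1000, "+"))]
        assert classify_pair(recs, config) == PairClass.CONCORDANT

    def test_cross_chromosome_discordant(self, config):
        recs = [make_record("r", 1, "chr1", 1000,
                            mate=mate_at("chr7", 5000, "-")),
                make_record("r", 2, "chr7", 5000, strand="-",
                            mate=mate_at("chr1", 1000, "+"))]
        assert classify_pair(recs, config) == PairClass.DISCORDANT

    def test_long_split_is_chimeric(self, config):
        recs = [make_record("r", 1, "chr2", 1_000_000, aligned=50, clip3=50,
                            read_len=100),
                make_record("r", 1, "chr2", 6_000_000, aligned=50, clip5=50,
                            read_len=100, supplementary=True)]
        assert classify_pair(recs, config) == PairClass.CHIMERIC

    def test_corrupt_fragment_fatal(self, config):
        recs = [make_record("r", 3, "chr1", 1000)]
        with pytest.raises(ValueError):
            classify_pair(recs, config)


class TestCallBreakpoints:
    def test_single_chimeric_read_tier1(self, config):
        recs = [make_record("x", 1, "chr1", 1000, aligned=50, clip3=50,
                            read_len=100),
                make_record("x", 1, "chr2", 8000, aligned=50, clip5=50,
                            read_len=100, supplementary=True)]
        calls = call_breakpoints(AlignmentStore(recs), config)
        assert len(calls) == 1
        assert calls[0].tier == 1
        assert (calls[0].chrom, calls[0].pos) == ("chr1", 1050)
        assert calls[0].orientation == LEFT_ANCHORED

    @pytest.mark.parametrize("n_neighbors,expect_call", [(2, True),
                                                         (1, False)])
    def test_tier2_needs_t1_neighbors(self, config, n_neighbors, expect_call):
        # clip 20 == l_min for read_len 100, kmer 15
        recs = [make_record("x", 1, "chr1", 1000, aligned=80, clip3=20,
                            read_len=100, mate=mate_at("chr9", 500, "-"))]
        for i in range(n_neighbors):
            recs.append(make_record(f"n{i}", 1, "chr1", 1010 + i,
                                    mate=mate_at("chr9", 510, "-")))
        calls = [c for c in call_breakpoints(AlignmentStore(recs), config)
                 if c.tier == 2]
        assert bool(calls) == expect_call
        if expect_call:
            assert calls[0].pos == 1080

    @pytest.mark.parametrize("n_pairs,expect", [(4, True), (3, False)])
    def test_tier4_group_threshold(self, config, n_pairs, expect):
        recs = [make_record(f"p{i}", 1, "chr1", 2000 + 10 * i,
                            mate=mate_at("chr5", 7000, "-"))
                for i in range(n_pairs)]
        calls = call_breakpoints(AlignmentStore(recs), config)
        assert bool(calls) == expect
        if expect:
            (c,) = calls
            assert c.tier == 4
            # farthest 3' extension of + strand reads: max end
            assert c.pos == 2000 + 10 * (n_pairs - 1) + 100

    def test_chimeric_never_downgraded(self, config):
        # read satisfying criterion (1) must not be reported at tier >= 2
        recs = [make_record("x", 1, "chr1", 1000, aligned=60, clip3=40,
                            read_len=100, mate=mate_at("chr9", 500, "-")),
                make_record("x", 1, "chr9", 480, aligned=40, clip5=60,
                            read_len=100, supplementary=True,
                            mate=mate_at("chr9", 500, "-"))]
        for i in range(4):
            recs.append(make_record(f"n{i}", 1, "chr1", 1010 + i,
                                    mate=mate_at("chr9", 510, "-")))
        x_calls = [c for c in call_breakpoints(AlignmentStore(recs), config)
                   if "x" in c.support_ids]
        assert all(c.tier == 1 for c in x_calls)


class TestGroupingAndRegions:
    def _call(self, pos, tier=1, n_support=1):
        from refusion.breakpoint_scan import BreakpointCall
        return BreakpointCall(chrom="chr1", pos=pos, tier=tier,
                              orientation=LEFT_ANCHORED,
                              support_ids=frozenset(
                                  f"s{pos}_{i}" for i in range(n_support)))

    @pytest.mark.parametrize("dist,n_groups", [(150, 1), (200, 1), (201, 2)])
    def test_group_distance_boundary(self, config, dist, n_groups):
        groups = merge_calls([self._call(1000), self._call(1000 + dist)],
                             None, config)
        assert len(groups) == n_groups

    def test_repeat_calls_removed_before_grouping(self, config):
        rep = IntervalSet([("chr1", 990, 1010)], label="repeat")
        groups = merge_calls([self._call(1000, tier=4),
                              self._call(1100, tier=4)], rep, config)
        assert len(groups) == 1
        assert groups[0].representative.pos == 1100

    def test_representative_strongest_evidence(self, config):
        groups = merge_calls([self._call(1000, tier=4),
                              self._call(1050, tier=1)], None, config)
        assert groups[0].representative.tier == 1

    def test_region_window_and_clipping(self, config):
        groups = merge_calls([self._call(10_000)], None, config)
        (region,) = candidate_regions(groups, {"chr1": 1_000_000}, config)
        assert region.window == (9750, 10250)
        groups = merge_calls([self._call(100)], None, config)
        (region,) = candidate_regions(groups, {"chr1": 1_000_000}, config)
        assert region.window == (0, 350)
        assert candidate_regions([], {"chr1": 100}, config) == []

    def test_region_contains_representative(self, rng, config):
        for _ in range(10):
            records = random_record_set(rng)
            calls = call_breakpoints(AlignmentStore(records), config)
            groups = merge_calls(calls, None, config)
            regions = candidate_regions(groups, {"chr1": 10**6,
                                                 "chr2": 10**6}, config)
            for r in regions:
                assert r.start <= r.representative.pos <= r.end
                assert r.end - r.start <= 500
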