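"""Spanning/encompassing support, the Spanning Score, gating, ranking,
final filtration, isoform merging and Intra/Inter + frame classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from refusion.fusion_calling import (FusionCandidate, SpanningEvidence,
                                     classify_candidate, collect_support,
                                     final_filter, merge_isoforms,
                                     rank_candidates, report_gate,
                                     spanning_score)
from refusion.io_model import Gene, GeneModel, ScanConfig, Transcript, revcomp
from refusion.junction_discovery import (Breakend, ChainedAlignment,
                                         JunctionCandidate)
from refusion.regional_assembly import Contig


def make_junction(rng, contig_len=300, brk=150, gene5="GA", gene3="GB",
                  chrom5="chr1", chrom3="chr2", pos5=849, pos3=900,
                  flags=(), q1=None, seq=None):
    seq = seq or random_dna(rng, contig_len)
    return JunctionCandidate(
        contig=Contig(seq=seq, k=21, support=5),
        gene5=gene5, gene3=gene3,
        break5=Breakend(chrom5, pos5, "+"), break3=Breakend(chrom3, pos3,
                                                            "+"),
        contig_break=brk,
        chained=ChainedAlignment(q0=contig_len,
                                 q1=q1 if q1 is not None else contig_len),
        flags=set(flags))


def make_candidate(rng, ss=2.0, enc=5, n_span=2, q1=None, flags=(),
                   gene5="GA", gene3="GB", pos5=849, pos3=900):
    j = make_junction(rng, flags=flags, q1=q1, gene5=gene5, gene3=gene3,
                      pos5=pos5, pos3=pos3)
    ev = SpanningEvidence()
    for i in range(n_span):
        ev.add(f"s{i}", 50, 50)
    return FusionCandidate(junction=j, spanning=ev, encompassing=enc, ss=ss)


class TestCollectSupport:
    @pytest.mark.parametrize("left,spanning", [(12, False), (13, True),
                                               (14, True)])
    def test_13nt_side_minimum(self, rng, left, spanning):
        j = make_junction(rng)
        read = j.contig.seq[j.contig_break - left:
                            j.contig_break - left + 100]
        ev, enc = collect_support(j, [("r1", read, None)])
        assert (ev.n == 1) == spanning
        if spanning:
            assert ev.entries[0][1:] == (left, 100 - left)

    def test_13_87_split(self, rng):
        j = make_junction(rng)
        read = j.contig.seq[j.contig_break - 13:j.contig_break + 87]
        ev, _ = collect_support(j, [("r1", read, None)])
        assert ev.entries[0][1:] == (13, 87)

    def test_pcr_duplicates_counted_once(self, rng):
        j = make_junction(rng)
        read = j.contig.seq[j.contig_break - 40:j.contig_break + 60]
        ev, _ = collect_support(j, [("r1", read, None), ("r2", read, None)])
        assert ev.n == 1

    def test_encompassing_pair(self, rng):
        j = make_junction(rng)
        b = j.contig_break
        left_read = j.contig.seq[b - 120:b - 20]
        right_read = revcomp(j.contig.seq[b + 20:b + 120])
        ev, enc = collect_support(j, [("r1", left_read, right_read)])
        assert ev.n == 0 and enc == 1

    def test_short_crossing_read_may_encompass_via_mate(self, rng):
        # 12 nt on one side: not spanning, but the pair still encompasses
        j = make_junction(rng)
        b = j.contig_break
        r1 = j.contig.seq[b - 112:b - 12]  # mostly left, crosses by 0
        r2 = revcomp(j.contig.seq[b - 12:b + 88])  # crosses with 12 left
        ev, enc = collect_support(j, [("r1", r1, r2)])
        assert ev.n == 0 and enc == 1

    def test_reverse_orientation_reads_found(self, rng):
        j = make_junction(rng)
        b = j.contig_break
        read = revcomp(j.contig.seq[b - 50:b + 50])
        ev, _ = collect_support(j, [("r1", read, None)])
        assert ev.n == 1 and ev.entries[0][1:] == (50, 50)


class TestSpanningScore:
    def test_balanced_single_read(self):
        ev = SpanningEvidence()
        ev.add("a", 50, 50)
        assert spanning_score(ev) == pytest.approx(1.0)

    def test_printed_example(self):
        ev = SpanningEvidence()
        for l, r in [(50, 50), (30, 70), (10, 90)]:
            ev.add(f"{l}", l, r)
        assert spanning_score(ev) == pytest.approx(1.8, abs=1e-12)

    def test_no_reads_zero(self):
        assert spanning_score(SpanningEvidence()) == 0

    @given(st.lists(st.tuples(st.integers(13, 87), st.integers(13, 87)),
                    min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounds_property(self, sides):
        # 0 < SS <= N, with equality exactly when every read is balanced
        ev = SpanningEvidence()
        for i, (l, r) in enumerate(sides):
            ev.add(f"r{i}", l, r)
        ss = spanning_score(ev)
        assert 0 < ss <= len(sides)
        if all(l == r for l, r in sides):
            assert ss == pytest.approx(len(sides))
        else:
            assert ss < len(sides)


class TestGateRankFilter:
    @pytest.mark.parametrize("n,enc,expect", [(1, 1, True), (1, 0, False),
                                              (0, 5, True), (0, 1, False)])
    def test_report_gate_two_supports(self, rng, n, enc, expect):
        c = make_candidate(rng, n_span=n, enc=enc)
        assert report_gate(c) == expect

    def test_rank_order_ss_enc_q(self, rng):
        a = make_candidate(rng, ss=2.0, enc=1, gene5="A1")
        b = make_candidate(rng, ss=1.5, enc=100, gene5="B1")
        assert rank_candidates([b, a]) == [a, b]
        c = make_candidate(rng, ss=1.5, enc=5, gene5="C1")
        d = make_candidate(rng, ss=1.5, enc=3, gene5="D1")
        assert rank_candidates([d, c]) == [c, d]
        e = make_candidate(rng, ss=1.5, enc=5, q1=290, gene5="E1")
        f = make_candidate(rng, ss=1.5, enc=5, q1=250, gene5="F1")
        assert rank_candidates([f, e]) == [e, f]

    @pytest.mark.parametrize("n_span,enc,ss,flags,kept", [
        (2, 2, 2.0, (), False),          # total 4 < 5
        (2, 3, 1.0, (), True),           # total 5, SS 1.0: boundary kept
        (2, 3, 0.99, (), False),         # SS < 1
        (10, 10, 3.0, ("repeat5", "selfchain3"), False),  # both sides
        (10, 10, 3.0, ("repeat5",), True),                # one side only
    ])
    def test_final_filter_rules(self, rng, n_span, enc, ss, flags, kept):
        c = make_candidate(rng, ss=ss, enc=enc, n_span=n_span, flags=flags)
        assert (final_filter([c]) == [c]) == kept

    def test_v1_repeat_rescue_rule(self, rng):
        strict = ScanConfig(v1_repeat_rescue=True)
        bare = make_candidate(rng, ss=3.0, enc=0, n_span=9,
                              flags=("repeat5",))
        rescued = make_candidate(rng, ss=3.0, enc=4, n_span=9,
                                 flags=("repeat5",))
        assert final_filter([bare], strict) == []
        assert final_filter([rescued], strict) == [rescued]
        assert final_filter([bare]) == [bare]  # v2 default keeps it

    def test_filter_idempotent_and_shrinking(self, rng):
        cands = [make_candidate(rng, ss=s, enc=e, n_span=n, gene5=f"G{i}")
                 for i, (s, e, n) in enumerate(
                     [(2.0, 3, 2), (0.5, 9, 1), (1.0, 1, 2), (3.0, 0, 9)])]
        once = final_filter(cands)
        assert len(once) <= len(cands)
        assert final_filter(once) == once
        assert all(report_gate(c) for c in once)


class TestMergeIsoforms:
    def test_two_isoform_junctions_merged(self, rng):
        a = make_candidate(rng, ss=3.0, pos5=849)
        b = make_candidate(rng, ss=2.0, pos5=700)
        merged = merge_isoforms([a, b])
        assert len(merged) == 1
        assert merged[0] is a  # best-ranked junction represents the pair
        assert len(merged[0].isoform_breakpoints) == 2

    def test_single_junction_unchanged(self, rng):
        a = make_candidate(rng)
        assert merge_isoforms([a]) == [a]

    def test_swapped_orientation_not_merged(self, rng):
        a = make_candidate(rng, gene5="GA", gene3="GB")
        b = make_candidate(rng, gene5="GB", gene3="GA")
        assert len(merge_isoforms([a, b])) == 2


class TestClassify:
    def _model(self):
        # two genes, single-exon CDS starting at 1000 and 5000
        ga = Gene(id="GA", name="GA", chrom="chr2", strand="+", start=900,
                  end=2100)
        ga.transcripts["GA.t1"] = Transcript(
            id="GA.t1", gene_id="GA", chrom="chr2", strand="+",
            exons=[(900, 2100)], cds=[(1000, 2000)])
        gb = Gene(id="GB", name="GB", chrom="chr2", strand="+", start=4900,
                  end=6100)
        gb.transcripts["GB.t1"] = Transcript(
            id="GB.t1", gene_id="GB", chrom="chr2", strand="+",
            exons=[(4900, 6100)], cds=[(5000, 6000)])
        return GeneModel([ga, gb])

    def test_intra_and_in_frame(self, rng):
        # 300 coding bases retained; resume at coding offset 450: both 0 mod 3
        c = make_candidate(rng)
        c.junction.break5 = Breakend("chr2", 1000 + 299, "+")
        c.junction.break3 = Breakend("chr2", 5000 + 450, "+")
        assert classify_candidate(c, self._model()) == ("Intra", "IF")

    def test_out_of_frame(self, rng):
        c = make_candidate(rng)
        c.junction.break5 = Breakend("chr2", 1000 + 299, "+")
        c.junction.break3 = Breakend("chr2", 5000 + 451, "+")
        assert classify_candidate(c, self._model()) == ("Intra", "OF")

    def test_inter_chromosomal(self, rng):
        c = make_candidate(rng)
        c.junction.break5 = Breakend("chr1", 1500, "+")
        c.junction.break3 = Breakend("chr2", 5450, "+")
        model = self._model()
        assert classify_candidate(c, model)[0] == "Inter"

    def test_utr_breakpoint_frame_na(self, rng):
        c = make_candidate(rng)
        c.junction.break5 = Breakend("chr2", 950, "+")  # 5' UTR
        c.junction.break3 = Breakend("chr2", 5450, "+")
        assert classify_candidate(c, self._model())[1] == "NA"
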