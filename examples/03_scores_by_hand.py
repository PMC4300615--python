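"""The two scores of the method, evaluated on hand-sized inputs.

The Spanning Score SS = N - sum |L-R|/(L+R) over the N spanning reads; the
alignment score Q = exp((q1-q0)/10) - exp((q2-q0)/10) contrasts a contig's
best and second-best chained genome alignments.
"""

from refusion.fusion_calling import SpanningEvidence, spanning_score
from refusion.junction_discovery import ChainedAlignment

ev = SpanningEvidence()
for read_id, left, right in [("a", 50, 50), ("b", 30, 70), ("c", 10, 90)]:
    ev.add(read_id, left, right)
print(f"SS of three spanning reads (50|50, 30|70, 10|90): "
      f"{spanning_score(ev):.4f}")
# 1.8: each read contributes 1 minus its imbalance |L-R|/(L+R), so three
# reads score below 3 unless all cross the junction dead-centre.

chained = ChainedAlignment(q0=100, q1=95, q2=80)
print(f"Q for a 100 nt contig with chain scores 95 and 80: "
      f"{chained.Q:.4f}")
# 0.4712 = e^-0.5 - e^-2: high when the best chain is near-perfect and the
# runner-up is clearly worse; a Q near 0 marks an ambiguous contig.

perfect = ChainedAlignment(q0=100, q1=100)
print(f"Q for a perfect, unambiguous alignment: {perfect.Q:.4f}")
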