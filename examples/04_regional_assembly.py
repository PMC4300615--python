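"""Assemble a junction-spanning contig from raw reads with the internal
de Bruijn assembler.

A 400 nt template stands in for a fusion neighbourhood; error-free pairs
tile it, one read carries a sequencing error, and the assembler's coverage
pruning removes the error branch.
"""

import numpy as np

from refusion.io_model import revcomp
from refusion.regional_assembly import assemble

rng = np.random.default_rng(5)
template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])

reads = []
starts = list(range(0, 400 - 75 + 1, 7)) + [400 - 75]  # cover the tail too
for start in starts:
    reads.append(template[start:start + 75])
    reads.append(revcomp(template[start:start + 75]))
bad = list(reads[6])
bad[30] = "A" if bad[30] != "A" else "C"  # one substitution error
reads.append("".join(bad))

contigs = assemble(reads, k=21, min_kmer_cov=2)
print(f"{len(reads)} reads -> {len(contigs)} contig(s)")
for c in contigs:
    recovered = template in (c.seq, revcomp(c.seq))
    print(f"  length {len(c.seq)}, read support {c.support}, "
          f"template recovered: {recovered}")
# One contig equal to the template (up to reverse complement): k-mers seen
# only once - here, the error k-mers - are pruned before path extraction.
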