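"""Shared fixtures: record builders, tiny SAM/GTF writers, a seeded world."""

from __future__ import annotations

import numpy as np
import pytest

from refusion.io_model import AlignmentRecord, MateInfo, ScanConfig


def make_record(read_id="r1", end=1, chrom="chr1", start=1000, aligned=100,
                strand="+", clip5=0, clip3=0, supplementary=False,
                mate=None, mapq=60, read_len=None, seq=None):
    """Compact AlignmentRecord factory for scan-level tests."""
    read_len = read_len if read_len is not None else aligned + clip5 + clip3
    return AlignmentRecord(
        read_id=read_id, fragment_end=end, chrom=chrom, start=start,
        end=start + aligned, strand=strand, aligned_len=aligned,
        clip5=clip5, clip3=clip3, is_supplementary=supplementary,
        segment_group=f"{read_id}/{end}", mate=mate, mapq=mapq,
        read_len=read_len, seq=seq)


def mate_at(chrom="chr2", start=5000, strand="-"):
    return MateInfo(chrom=chrom, start=start, strand=strand)


@pytest.fixture
def config():
    return ScanConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_sam(path, records, chroms=(("chr1", 100000), ("chr2", 100000))):
    """Write a minimal SAM text file from (qname, flag, chrom, pos1, mapq,
    cigar, rnext, pnext, seq, tags) tuples; pos1 is 1-based."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in chroms:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for rec in records:
        qname, flag, chrom, pos1, mapq, cigar, rnext, pnext, seq = rec[:9]
        tags = rec[9] if len(rec) > 9 else []
        qual = "*" if seq == "*" else "I" * len(seq)
        fields = [qname, str(flag), chrom, str(pos1), str(mapq), cigar,
                  rnext, str(pnext), "0", seq, qual] + list(tags)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
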