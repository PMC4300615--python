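"""End-to-end fusion detection: scan -> regions -> assembly -> junctions ->
support -> filter/rank/merge -> report.

The pipeline is a pure function of its inputs and configuration: two runs on
identical inputs produce byte-identical reports, independent of the worker
count used for per-region assembly.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import breakpoint_scan, fusion_calling, junction_discovery
from .io_model import (AlignmentStore, GeneModel, IntervalSet, ScanConfig,
                       load_gene_model, load_interval_set, write_report)
from .junction_discovery import GenomeIndex
from .regional_assembly import assemble, extract_anchored_pairs

logger = logging.getLogger(__name__)


@dataclass
class DetectResult:
    candidates: list
    counts: dict = field(default_factory=dict)
    report_path: Optional[Path] = None


def _assemble_task(args):
    sequences, k, min_cov, region_id = args
    return assemble(sequences, k=k, min_kmer_cov=min_cov,
                    region_id=region_id)


def detect(bam, ref, genes, out=None, repeats=None, selfchain=None,
           config: Optional[ScanConfig] = None, contigs_from=None,
           n_workers: int = 1) -> DetectResult:
    """Run the full detection pipeline on aligned reads.

    Parameters mirror the external inputs: ``bam`` (SAM/BAM alignments),
    ``ref`` (genome FASTA), ``genes`` (GTF/BED12), optional ``repeats`` and
    ``selfchain`` BEDs, and an optional contig FASTA (``contigs_from``) that
    bypasses the internal assembler.  When ``out`` is given the ranked
    report is written there as TSV.
    """
    config = config or ScanConfig()
    store = AlignmentStore.load(bam, min_mapq=config.min_mapq)
    gene_model = load_gene_model(genes)
    repeat_set = (load_interval_set(repeats, "repeat") if repeats
                  else IntervalSet(label="repeat"))
    selfchain_set = (load_interval_set(selfchain, "selfchain") if selfchain
                     else IntervalSet(label="selfchain"))
    genome = GenomeIndex.from_fasta(ref, seed=config.min_seed)

    calls = breakpoint_scan.call_breakpoints(store, config)
    groups = breakpoint_scan.merge_calls(calls, repeat_set, config)
    regions = breakpoint_scan.candidate_regions(groups, genome.lengths,
                                                config)
    logger.info("scan: %d calls, %d groups, %d regions",
                len(calls), len(groups), len(regions))

    anchored_sets = [extract_anchored_pairs(r, store, config=config)
                     for r in regions]
    if contigs_from is not None:
        # external contigs are offered to every region so each region's
        # anchored pairs can support the junctions they cover
        ext = _load_contig_fasta(contigs_from, config.assembly_k)
        contig_lists = [list(ext) for _ in anchored_sets]
    else:
        tasks = [(a.sequences, config.assembly_k, config.min_kmer_cov,
                  f"{a.region.chrom}:{a.region.start}-{a.region.end}")
                 for a in anchored_sets]
        if n_workers > 1 and len(tasks) > 1:
            with ProcessPoolExecutor(max_workers=n_workers) as pool:
                contig_lists = list(pool.map(_assemble_task, tasks))
        else:
            contig_lists = [_assemble_task(t) for t in tasks]
        # keep the best-supported contigs per region
        contig_lists = [cl[:5] for cl in contig_lists]
    n_contigs = sum(len(cl) for cl in contig_lists)
    logger.info("assembly: %d contigs", n_contigs)

    junctions = _discover_junctions(contig_lists, anchored_sets, genome,
                                    gene_model, repeat_set, selfchain_set,
                                    config)
    logger.info("junctions: %d candidates", len(junctions))

    raw = []
    for junction, pair_lists in junctions:
        merged_pairs = _merge_pairs(pair_lists)
        spanning, enc = fusion_calling.collect_support(junction, merged_pairs,
                                                       config)
        raw.append(fusion_calling.FusionCandidate(
            junction=junction, spanning=spanning, encompassing=enc))
    final = fusion_calling.finalize_candidates(raw, gene_model, config)
    logger.info("reported: %d fusions", len(final))

    report_path = None
    if out is not None:
        report_path = Path(out)
        write_report(final, report_path, config)
    counts = {"calls": len(calls), "groups": len(groups),
              "regions": len(regions), "contigs": n_contigs,
              "junction_candidates": len(junctions),
              "reported": len(final)}
    return DetectResult(candidates=final, counts=counts,
                        report_path=report_path)


def _discover_junctions(contig_lists, anchored_sets, genome, gene_model,
                        repeat_set, selfchain_set, config):
    """Realign/chain each region's contigs and deduplicate junctions found
    from both partner regions, pooling their anchored read pairs."""
    found: dict[tuple, list] = {}
    order: list[tuple] = []
    for contigs, anchored in zip(contig_lists, anchored_sets):
        for contig in contigs:
            segs = junction_discovery.realign_contig(
                contig, genome, min_seed=config.min_seed,
                nonunique_frac=config.nonunique_frac)
            chained = junction_discovery.chain_paths(
                segs, len(contig.seq), max_overlap=config.max_overlap)
            jc = junction_discovery.detect_junction(
                chained, contig, gene_model,
                (repeat_set, selfchain_set), config, genome=genome)
            if jc is None:
                continue
            key = (jc.gene5, jc.gene3, jc.break5.chrom, jc.break5.pos,
                   jc.break3.chrom, jc.break3.pos)
            if key not in found:
                found[key] = [jc, [anchored.pairs]]
                order.append(key)
            else:
                kept = found[key][0]
                if jc.Q > kept.Q:
                    found[key][0] = jc
                found[key][1].append(anchored.pairs)
    return [(found[k][0], found[k][1]) for k in order]


def _merge_pairs(pair_lists):
    seen = set()
    merged = []
    for pairs in pair_lists:
        for rid, s1, s2 in pairs:
            if rid in seen:
                continue
            seen.add(rid)
            merged.append((rid, s1, s2))
    merged.sort(key=lambda p: p[0])
    return merged


def _load_contig_fasta(path, k):
    from .regional_assembly import Contig

    contigs = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None and chunks:
                    contigs.append(Contig(seq="".join(chunks), k=k,
                                          support=0, region_id=name))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None and chunks:
        contigs.append(Contig(seq="".join(chunks), k=k, support=0,
                              region_id=name))
    return contigs


def simulate(config, outdir):
    """Convenience front-end to :func:`refusion.synthetic_data.simulate`."""
    from . import synthetic_data

    return synthetic_data.simulate(config, outdir)
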