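"""End-to-end insertion calling: evidence -> alleles -> refined calls.

Runs the full pipeline over an indexed alignment file: library
statistics, evidence extraction and clustering, the three
allele-construction engines per candidate site, arbitration between
their results, breakpoint refinement, deduplication, filtering and VCF
emission.
"""

from __future__ import annotations

from dataclasses import replace

import pysam

from ._align import KmerIndex
from .core_io import (DEFAULT_MIN_INSERTION_SIZE, InsertionCall, LibraryStats,
                      estimate_library_stats, fetch_reference,
                      reference_contigs, write_vcf)
from .evidence import CandidateSite, cluster_sites, extract_evidence
from .finalize import AltAllele, apply_filters, refine_breakpoints
from .novel_assembly import assemble, orient_reads
from .small_insertion import MAX_BP_GAP, build_clip_consensus, overlap_call
from .transposition_remap import find_source_region, guided_assemble

_ORIGIN_PRIORITY = {"remap": 0, "denovo": 1, "clip": 2}
DEDUP_WINDOW = 10


def _fill_flanks(allele: AltAllele, site: CandidateSite, reference,
                 stats: LibraryStats) -> AltAllele | None:
    """Complete a de novo allele with reference flanks at the junctions."""
    def bp(reads, attr, fallback):
        vals = sorted(getattr(e, attr) for e in reads)
        return vals[len(vals) // 2] if vals else fallback

    lo, hi = site.anchor_interval
    bp_left = bp(site.clipped_left, "end", hi)
    bp_right = bp(site.clipped_right, "start", bp_left)
    flank = 2 * stats.read_length
    contig_len = reference_contigs(reference)[site.contig]
    if bp_left < 1 or bp_right < 1:
        return None
    return replace(
        allele, contig=site.contig,
        left_flank=fetch_reference(reference, site.contig,
                                   max(0, bp_left - flank), bp_left),
        right_flank=fetch_reference(reference, site.contig, bp_right,
                                    min(contig_len, bp_right + flank)),
        left_flank_end=bp_left, right_flank_start=bp_right,
        support_left=site.support_left, support_right=site.support_right)


def _site_alleles(site: CandidateSite, reference, stats: LibraryStats,
                  kmer_index: KmerIndex,
                  min_insertion_size: int) -> list[AltAllele]:
    alleles: list[AltAllele] = []
    left_unstable, right_unstable = site.unstable_sequences()

    left_cons = build_clip_consensus(site.clipped_left, "right")
    right_cons = build_clip_consensus(site.clipped_right, "left")

    # reference-guided remap of the unstable reads
    if len(left_unstable) + len(right_unstable) >= 3:
        source = find_source_region(site, reference, kmer_index,
                                    read_length=stats.read_length)
        if source is not None:
            allele = guided_assemble(site, source, reference, stats)
            if allele is not None:
                alleles.append(allele)

    # strand-aware de novo assembly
    left_pool, right_pool = orient_reads(site)
    if len(left_pool) >= 2 and len(right_pool) >= 2:
        left_seed = left_cons[0].clip_consensus if left_cons else None
        right_seed = right_cons[0].clip_consensus if right_cons else None
        allele = assemble(left_pool, right_pool, left_seed=left_seed,
                          right_seed=right_seed)
        if allele is not None:
            allele = _fill_flanks(allele, site, reference, stats)
            if allele is not None:
                alleles.append(allele)

    # clip-consensus overlap for small insertions
    for lc in left_cons:
        for rc in right_cons:
            if abs(lc.breakpoint - rc.breakpoint) > MAX_BP_GAP:
                continue
            allele = overlap_call(lc, rc,
                                  min_insertion_size=min_insertion_size)
            if allele is not None:
                alleles.append(allele)
    return alleles


def _call_rank(call: InsertionCall, origin: str) -> tuple:
    return (0 if call.complete else 1,
            -(call.support_left + call.support_right),
            _ORIGIN_PRIORITY.get(origin, 9))


def call_contig(alignment, reference, contig: str, stats: LibraryStats,
                kmer_index: KmerIndex,
                min_insertion_size: int = DEFAULT_MIN_INSERTION_SIZE,
                ) -> list[InsertionCall]:
    """Call insertions on one contig; returns unfiltered, refined calls."""
    evidence = extract_evidence(alignment, stats,
                                region=(contig, 0,
                                        reference_contigs(reference)[contig]))
    evidence = [e for e in evidence if e.contig == contig]
    sites = cluster_sites(evidence, stats)
    candidates: list[tuple[InsertionCall, str]] = []
    for site in sites:
        best = None
        for allele in _site_alleles(site, reference, stats, kmer_index,
                                    min_insertion_size):
            call = refine_breakpoints(allele, site, reference, stats,
                                      min_insertion_size)
            if call is None:
                continue
            rank = _call_rank(call, allele.origin)
            if best is None or rank < best[0]:
                best = (rank, call, allele.origin)
        if best is not None:
            candidates.append((best[1], best[2]))

    # deduplicate nearby calls (the same insertion reported by two sites)
    candidates.sort(key=lambda co: co[0].pos)
    deduped: list[tuple[InsertionCall, str]] = []
    for call, origin in candidates:
        if deduped and call.pos - deduped[-1][0].pos <= DEDUP_WINDOW:
            if _call_rank(call, origin) < _call_rank(deduped[-1][0],
                                                     deduped[-1][1]):
                deduped[-1] = (call, origin)
            continue
        deduped.append((call, origin))
    return [c for c, _ in deduped]


def call_insertions(bam_path: str, reference,
                    min_insertion_size: int = DEFAULT_MIN_INSERTION_SIZE,
                    exclude_regions=None, sample_id: str = "",
                    hard_filter: bool = False,
                    stats: LibraryStats | None = None,
                    ) -> tuple[list[InsertionCall], LibraryStats]:
    """Run the whole pipeline on an indexed BAM/CRAM.

    Returns the filtered calls (sorted by contig and position) and the
    estimated library statistics.
    """
    contigs = {name: fetch_reference(reference, name)
               for name in reference_contigs(reference)}
    kmer_index = KmerIndex(contigs)
    with pysam.AlignmentFile(bam_path) as alignment:
        if stats is None:
            stats = estimate_library_stats(alignment)
        calls: list[InsertionCall] = []
        for contig in contigs:
            calls.extend(call_contig(alignment, reference, contig, stats,
                                     kmer_index, min_insertion_size))
        for call in calls:
            call.sample_id = sample_id
        calls = apply_filters(calls, stats, exclude_regions=exclude_regions,
                              min_insertion_size=min_insertion_size,
                              alignment_source=alignment,
                              hard_filter=hard_filter)
    order = {name: i for i, name in enumerate(contigs)}
    calls.sort(key=lambda c: (order[c.contig], c.pos))
    return calls, stats


def call_to_vcf(bam_path: str, reference, out_vcf: str, **kwargs) -> int:
    """Convenience wrapper: run the pipeline and write a VCF."""
    calls, _ = call_insertions(bam_path, reference, **kwargs)
    write_vcf(calls, reference, out_vcf)
    return len(calls)
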