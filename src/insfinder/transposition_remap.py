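"""Reference-guided detection of transposition-like insertions.

When the inserted sequence is (nearly) identical to a region elsewhere
in the reference — the mobile-element scenario — the unstable reads of
a candidate site can be remapped genome-wide to locate that source
region.  The source then serves as a backbone for a reference-guided
consensus: reads vote per column, so divergence between the inserted
copy and its source (the typical few-percent for transposed elements)
is recovered rather than reporting the source sequence verbatim.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._align import (KmerIndex, local_align, local_align_blocks,
                     make_local_aligner, revcomp)
from .core_io import LibraryStats, fetch_reference, reference_contigs
from .evidence import CandidateSite
from .finalize import AltAllele

MIN_SUPPORT_SOURCE = 3
MIN_SOURCE_IDENTITY = 0.85
MIN_READ_COVERAGE = 0.80
MIN_ANCHOR_TAIL = 20

_READ_ALIGNER = make_local_aligner(match=1, mismatch=-2, gap_open=-4)


@dataclass(frozen=True)
class SourceRegion:
    """Reference region identified as the origin of an inserted sequence."""

    contig: str
    start: int
    end: int
    orientation: str  # 'forward' or 'reverse'
    supporting_reads: int
    mean_identity: float


def find_source_region(site: CandidateSite, reference,
                       kmer_index: KmerIndex | None = None,
                       read_length: int = 150,
                       min_support: int = MIN_SUPPORT_SOURCE,
                       ) -> SourceRegion | None:
    """Locate the reference region the unstable reads were copied from.

    Unstable mate sequences (in insertion-forward frame) are seeded
    genome-wide on both strands via a k-mer index, seed hits are
    clustered by position, and the largest cluster is verified read by
    read with a local aligner (identity >= 0.85 over >= 80% of the
    read).  Returns None when no cluster gathers ``min_support``
    verified reads.  Ties between equally supported clusters go to the
    leftmost genomic coordinate.
    """
    left, right = site.unstable_sequences()
    seqs = left + right
    if len(seqs) < min_support:
        return None
    if kmer_index is None:
        contigs = {name: fetch_reference(reference, name)
                   for name in reference_contigs(reference)}
        kmer_index = KmerIndex(contigs)

    # seed anchors: estimated start position of each read on the reference
    anchors: list[tuple[str, int, int, str]] = []  # (contig, pos, read_idx, strand)
    for idx, seq in enumerate(seqs):
        for strand, s in (("forward", seq), ("reverse", revcomp(seq))):
            seen = set()
            for off, contig, pos in kmer_index.seeds(s):
                anchor = pos - off
                key = (contig, anchor // 50, strand)
                if key in seen:
                    continue
                seen.add(key)
                anchors.append((contig, anchor, idx, strand))
    if not anchors:
        return None

    # single-linkage clustering of anchors along the genome
    anchors.sort(key=lambda a: (a[0], a[1]))
    clusters: list[list[tuple[str, int, int, str]]] = []
    for a in anchors:
        if clusters and a[0] == clusters[-1][-1][0] \
                and a[1] - clusters[-1][-1][1] <= read_length:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    clusters.sort(key=lambda c: (-len({a[2] for a in c}), c[0][0], c[0][1]))

    lengths = reference_contigs(reference)
    for cluster in clusters[:3]:
        if len({a[2] for a in cluster}) < min_support:
            break
        contig = cluster[0][0]
        lo = max(0, min(a[1] for a in cluster) - read_length)
        hi = min(lengths[contig],
                 max(a[1] for a in cluster) + 2 * read_length)
        region_seq = fetch_reference(reference, contig, lo, hi)
        identities, orient_votes = [], Counter()
        span_lo, span_hi = hi, lo
        supported = set()
        for idx, seq in enumerate(seqs):
            best = None
            for strand, s in (("forward", seq), ("reverse", revcomp(seq))):
                hit = local_align(s, region_seq, _READ_ALIGNER)
                if hit is None:
                    continue
                if best is None or hit.score > best[0].score:
                    best = (hit, strand)
            if best is None:
                continue
            hit, strand = best
            if hit.identity >= MIN_SOURCE_IDENTITY \
                    and hit.query_coverage(len(seq)) >= MIN_READ_COVERAGE:
                supported.add(idx)
                identities.append(hit.identity)
                orient_votes[strand] += 1
                span_lo = min(span_lo, lo + hit.t_start)
                span_hi = max(span_hi, lo + hit.t_end)
        if len(supported) >= min_support:
            mean_identity = sum(identities) / len(identities)
            if mean_identity < MIN_SOURCE_IDENTITY:
                continue
            orientation = "forward"
            if orient_votes["reverse"] > orient_votes["forward"]:
                orientation = "reverse"
            return SourceRegion(
                contig=contig,
                start=max(0, span_lo - read_length),
                end=min(lengths[contig], span_hi + read_length),
                orientation=orientation,
                supporting_reads=len(supported),
                mean_identity=mean_identity)
    return None


def _breakpoint_consensus(reads, attr: str) -> int | None:
    vals = sorted(getattr(e, attr) for e in reads)
    if not vals:
        return None
    return vals[len(vals) // 2]


def guided_assemble(site: CandidateSite, source: SourceRegion, reference,
                    stats: LibraryStats,
                    min_alt_votes: int = 2,
                    min_alt_fraction: float = 0.70) -> AltAllele | None:
    """Reference-guided consensus of the inserted sequence.

    All unstable mates and clip tails are aligned to the extracted
    source sequence (reverse-complemented when the source orientation is
    reverse, so the backbone reads in insertion-forward frame).  Each
    aligned column votes; a non-reference base is adopted when supported
    by >= ``min_alt_votes`` reads making up >= ``min_alt_fraction`` of
    the column's coverage.  The insertion's extent within the backbone
    is anchored by the junction clip tails, and the consensus is trimmed
    to read-covered positions: uncovered interior sequence makes the
    allele incomplete (prefix/suffix) rather than being back-filled from
    the source.
    """
    backbone = fetch_reference(reference, source.contig, source.start,
                               source.end)
    if source.orientation == "reverse":
        backbone = revcomp(backbone)
    if len(backbone) < 50:
        return None

    left_unstable, right_unstable = site.unstable_sequences()
    left_tails = [e.clip_seq for e in site.clipped_left
                  if e.clip_len >= MIN_ANCHOR_TAIL]
    right_tails = [e.clip_seq for e in site.clipped_right
                   if e.clip_len >= MIN_ANCHOR_TAIL]

    coverage = [0] * len(backbone)
    votes: list[Counter] = [Counter() for _ in range(len(backbone))]

    def add_read(seq: str) -> object | None:
        res = local_align_blocks(seq, backbone, _READ_ALIGNER)
        if res is None:
            return None
        hit, blocks = res
        if hit.identity < 0.80 or hit.query_coverage(len(seq)) < 0.5:
            return None
        for t0, t1, q0, q1 in blocks:
            for t, q in zip(range(t0, t1), range(q0, q1)):
                coverage[t] += 1
                votes[t][seq[q]] += 1
        return hit

    for seq in left_unstable + right_unstable:
        add_read(seq)

    # junction anchoring: left-junction tails start at the insertion's
    # first base, right-junction tails end at its last base
    starts, ends = [], []
    for tail in left_tails:
        hit = add_read(tail)
        if hit is not None and hit.q_start <= 2:
            starts.append(hit.t_start - hit.q_start)
    for tail in right_tails:
        hit = add_read(tail)
        if hit is not None and hit.q_end >= len(tail) - 2:
            ends.append(hit.t_end + (len(tail) - hit.q_end))
    if not starts or not ends:
        return None
    ins_start = max(0, sorted(starts)[len(starts) // 2])
    ins_end = min(len(backbone), sorted(ends)[len(ends) // 2])
    if ins_end - ins_start < 50:
        return None

    consensus = list(backbone)
    for t in range(ins_start, ins_end):
        if votes[t]:
            base, n = votes[t].most_common(1)[0]
            if base != backbone[t] and (
                    n < min_alt_votes or n < min_alt_fraction * coverage[t]):
                continue
            consensus[t] = base
    consensus_str = "".join(consensus)

    # trim to read-covered interval; completeness additionally demands
    # two-read coverage everywhere so that no consensus column is decided
    # by the backbone alone or by a single (possibly erroneous) read
    covered = [t for t in range(ins_start, ins_end) if coverage[t] > 0]
    if not covered:
        return None
    complete = all(coverage[t] >= 2 for t in range(ins_start, ins_end))

    bp_left = _breakpoint_consensus(site.clipped_left, "end")
    bp_right = _breakpoint_consensus(site.clipped_right, "start")
    if bp_left is None or bp_right is None:
        return None
    flank = 2 * stats.read_length
    contig_len = reference_contigs(reference)[site.contig]
    left_flank = fetch_reference(reference, site.contig,
                                 max(0, bp_left - flank), bp_left)
    right_flank = fetch_reference(reference, site.contig, bp_right,
                                  min(contig_len, bp_right + flank))

    common = dict(contig=site.contig, left_flank=left_flank,
                  right_flank=right_flank, left_flank_end=bp_left,
                  right_flank_start=bp_right, origin="remap",
                  support_left=site.support_left,
                  support_right=site.support_right)
    if complete:
        return AltAllele(complete=True,
                         inserted=consensus_str[ins_start:ins_end], **common)
    # contiguous covered run from each junction
    pref_end = ins_start
    while pref_end < ins_end and coverage[pref_end] > 0:
        pref_end += 1
    suf_start = ins_end
    while suf_start > ins_start and coverage[suf_start - 1] > 0:
        suf_start -= 1
    prefix = consensus_str[ins_start:pref_end]
    suffix = consensus_str[suf_start:ins_end]
    if not prefix or not suffix:
        return None
    return AltAllele(complete=False, ins_prefix=prefix, ins_suffix=suffix,
                     **common)
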