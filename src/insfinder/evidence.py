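"""Evidence extraction and candidate-site clustering.

Insertions leave two read-level footprints in a paired-end library: a
discordant pair, where one mate (the *stable* read) aligns to the flank
of the insertion site while its partner (the *unstable* read) was
sequenced from the inserted sequence and is unmapped or maps elsewhere;
and soft-clipped reads whose clipped tail carries the start or end of
the inserted sequence.  Stable reads are clustered by position and
strand — forward-strand stable reads sit upstream of the insertion,
reverse-strand ones downstream — and paired into candidate sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from ._align import revcomp
from .core_io import InputError, LibraryStats

MIN_CLIP_LEN = 15
MIN_MAPQ_STABLE = 20
MIN_SUPPORT_ONE_SIDE = 3
MIN_CLIPPED = 3


@dataclass
class EvidenceRead:
    """One insertion-supporting alignment record.

    ``mate_seq``, when present, is the unstable mate's sequence stored
    in the orientation it was written to the alignment file;
    ``mate_seq_is_raw`` is True when that orientation is as-sequenced
    (the convention for unmapped mates) rather than reference-forward.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    role: str    # 'stable' or 'clipped'
    mapq: int
    mate_seq: str | None = None
    mate_seq_is_raw: bool = True
    clip_side: str = "none"  # 'left', 'right' or 'none'
    clip_len: int = 0
    clip_seq: str = ""
    anchor_seq: str = ""

    def __post_init__(self):
        if self.role == "clipped" and self.clip_side == "none":
            raise ValueError("clipped evidence requires a clip side")


@dataclass
class CandidateSite:
    """Paired stable-read clusters delimiting a putative insertion locus.

    ``anchor_interval`` spans from the end of the left (forward-strand)
    cluster to the start of the right (reverse-strand) cluster; for
    one-sided or clip-only sites it degenerates to the best local guess.
    ``clipped_left`` holds reads clipped at the *left junction* (i.e.
    right-soft-clipped, anchored on the left flank); ``clipped_right``
    the left-soft-clipped reads anchored on the right flank.
    """

    contig: str
    left_cluster: list[EvidenceRead] = field(default_factory=list)
    right_cluster: list[EvidenceRead] = field(default_factory=list)
    clipped_left: list[EvidenceRead] = field(default_factory=list)
    clipped_right: list[EvidenceRead] = field(default_factory=list)
    anchor_interval: tuple[int, int] = (0, 0)

    @property
    def support_left(self) -> int:
        return len(self.left_cluster) + len(self.clipped_left)

    @property
    def support_right(self) -> int:
        return len(self.right_cluster) + len(self.clipped_right)

    def unstable_sequences(self) -> tuple[list[str], list[str]]:
        """Unstable mate sequences in reference-forward frame.

        Returns (from_left, from_right): mates of forward-strand stable
        reads (sequenced 5'->3' into the insertion from the left
        junction) and mates of reverse-strand stable reads.  In an FR
        library the mate of a forward stable read lies on the opposite
        haplotype strand, so raw (as-sequenced) mate sequences from the
        left side are reverse-complemented into the forward frame.
        """
        left, right = [], []
        for ev in self.left_cluster:
            if ev.mate_seq:
                seq = revcomp(ev.mate_seq) if ev.mate_seq_is_raw else ev.mate_seq
                left.append(seq.upper())
        for ev in self.right_cluster:
            if ev.mate_seq:
                right.append(ev.mate_seq.upper())
        return left, right


def _clip_geometry(read: pysam.AlignedSegment) -> tuple[str, int]:
    """(side, length) of the longer terminal soft clip."""
    cigar = read.cigartuples
    left = cigar[0][1] if cigar[0][0] == 4 else 0
    right = cigar[-1][1] if cigar[-1][0] == 4 else 0
    if left >= right:
        return "left", left
    return "right", right


def extract_evidence(alignment_source, stats: LibraryStats,
                     region: tuple[str, int, int] | None = None,
                     min_mapq: int = MIN_MAPQ_STABLE,
                     min_clip_len: int = MIN_CLIP_LEN) -> list[EvidenceRead]:
    """Collect stable and clipped evidence reads.

    A primary, non-duplicate alignment with MAPQ >= ``min_mapq`` becomes
    *stable* evidence when its pair is discordant: mate unmapped, mate
    on another contig, template length outside the concordant range, or
    both mates on the same strand.  Reads soft-clipped by >=
    ``min_clip_len`` bases become *clipped* evidence.  A read may
    contribute both roles.

    Unstable mate sequences are captured from mate-unmapped records
    placed at the stable read's coordinate (the standard convention for
    unmapped-with-mapped-mate pairs).
    """
    own = False
    if isinstance(alignment_source, str):
        alignment_source = pysam.AlignmentFile(alignment_source)
        own = True
    try:
        if not alignment_source.has_index():
            raise InputError("alignment source must be indexed")
        if region is None:
            it = alignment_source.fetch()
        else:
            it = alignment_source.fetch(region[0], region[1], region[2])
        unmapped_seqs: dict[str, str] = {}
        pending: list[tuple[EvidenceRead, str]] = []  # stable ev awaiting mate seq
        out: list[EvidenceRead] = []
        for read in it:
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if read.is_unmapped:
                if read.query_sequence and not read.mate_is_unmapped:
                    unmapped_seqs[read.query_name] = read.query_sequence
                continue
            if read.mapping_quality < min_mapq:
                continue
            strand = "-" if read.is_reverse else "+"
            discordant = False
            if read.is_paired:
                if read.mate_is_unmapped:
                    discordant = True
                elif read.next_reference_id != read.reference_id:
                    discordant = True
                elif read.is_reverse == read.mate_is_reverse:
                    discordant = True
                elif read.template_length != 0 and not (
                        stats.min_concordant_insert
                        <= abs(read.template_length)
                        <= stats.max_concordant_insert):
                    discordant = True
            if discordant:
                ev = EvidenceRead(
                    read_id=read.query_name, contig=read.reference_name,
                    start=read.reference_start, end=read.reference_end,
                    strand=strand, role="stable", mapq=read.mapping_quality)
                if read.mate_is_unmapped:
                    pending.append((ev, read.query_name))
                out.append(ev)
            cigar = read.cigartuples
            if cigar and (cigar[0][0] == 4 or cigar[-1][0] == 4):
                side, clip_len = _clip_geometry(read)
                if clip_len >= min_clip_len:
                    seq = read.query_sequence
                    if side == "left":
                        clip_seq, anchor = seq[:clip_len], seq[clip_len:]
                    else:
                        clip_seq, anchor = seq[-clip_len:], seq[:-clip_len]
                    out.append(EvidenceRead(
                        read_id=read.query_name, contig=read.reference_name,
                        start=read.reference_start, end=read.reference_end,
                        strand=strand, role="clipped",
                        mapq=read.mapping_quality, clip_side=side,
                        clip_len=clip_len, clip_seq=clip_seq.upper(),
                        anchor_seq=anchor.upper()))
        for ev, qname in pending:
            ev.mate_seq = unmapped_seqs.get(qname)
        return out
    finally:
        if own:
            alignment_source.close()


def _greedy_position_clusters(reads: list[EvidenceRead],
                              max_gap: int) -> list[list[EvidenceRead]]:
    """Single-linkage clustering: consecutive starts within ``max_gap``."""
    clusters: list[list[EvidenceRead]] = []
    for ev in sorted(reads, key=lambda e: (e.start, e.end, e.read_id)):
        if clusters and ev.start - clusters[-1][-1].start <= max_gap:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    return clusters


def cluster_sites(evidence: list[EvidenceRead], stats: LibraryStats,
                  min_support_one_side: int = MIN_SUPPORT_ONE_SIDE,
                  min_clipped: int = MIN_CLIPPED) -> list[CandidateSite]:
    """Group stable reads into candidate insertion sites.

    Forward-strand stable reads form left clusters, reverse-strand ones
    right clusters (greedy single-linkage with gap up to the maximum
    concordant insert).  A left and a right cluster are paired into a
    two-sided site when the right cluster starts within
    ``[-read_length, max_concordant_insert]`` of the left cluster's
    end.  Unpaired clusters with enough members become one-sided sites;
    groups of clipped reads not attached to any site become clip-only
    sites when at least ``min_clipped`` strong.
    """
    if not evidence:
        return []
    contigs = {ev.contig for ev in evidence}
    if len(contigs) > 1:
        raise InputError("cluster_sites expects evidence from one contig")
    contig = contigs.pop()
    max_gap = stats.max_concordant_insert
    fwd = [e for e in evidence if e.role == "stable" and e.strand == "+"]
    rev = [e for e in evidence if e.role == "stable" and e.strand == "-"]
    clipped = [e for e in evidence if e.role == "clipped"]

    left_clusters = _greedy_position_clusters(fwd, max_gap)
    right_clusters = _greedy_position_clusters(rev, max_gap)

    sites: list[CandidateSite] = []
    used_right: set[int] = set()
    for lc in left_clusters:
        lc_end = max(e.end for e in lc)
        best = None
        for ri, rc in enumerate(right_clusters):
            if ri in used_right:
                continue
            rc_start = min(e.start for e in rc)
            gap = rc_start - lc_end
            if -stats.read_length <= gap <= max_gap:
                if best is None or rc_start < best[1]:
                    best = (ri, rc_start)
        if best is not None:
            ri, rc_start = best
            used_right.add(ri)
            rc = right_clusters[ri]
            sites.append(CandidateSite(
                contig=contig, left_cluster=lc, right_cluster=rc,
                anchor_interval=(min(lc_end, rc_start), max(lc_end, rc_start))))
        elif len(lc) >= min_support_one_side:
            sites.append(CandidateSite(
                contig=contig, left_cluster=lc,
                anchor_interval=(lc_end, lc_end + max_gap)))
    for ri, rc in enumerate(right_clusters):
        if ri in used_right:
            continue
        if len(rc) >= min_support_one_side:
            rc_start = min(e.start for e in rc)
            sites.append(CandidateSite(
                contig=contig, right_cluster=rc,
                anchor_interval=(max(0, rc_start - max_gap), rc_start)))

    # attach clipped reads to the nearest site within the insert range
    def breakpoint_of(ev: EvidenceRead) -> int:
        return ev.end if ev.clip_side == "right" else ev.start

    unattached: list[EvidenceRead] = []
    sites.sort(key=lambda s: s.anchor_interval)
    for ev in clipped:
        bp = breakpoint_of(ev)
        best = None
        for site in sites:
            lo, hi = site.anchor_interval
            dist = 0 if lo <= bp <= hi else min(abs(bp - lo), abs(bp - hi))
            if dist <= max_gap and (best is None or dist < best[0]):
                best = (dist, site)
        if best is None:
            unattached.append(ev)
        elif ev.clip_side == "right":
            best[1].clipped_left.append(ev)
        else:
            best[1].clipped_right.append(ev)

    # clip-only sites from the remaining clipped reads
    by_bp = sorted(unattached, key=lambda e: (breakpoint_of(e), e.read_id))
    group: list[EvidenceRead] = []

    def flush(group: list[EvidenceRead]):
        if len(group) >= min_clipped:
            bps = [breakpoint_of(e) for e in group]
            lo, hi = min(bps), max(bps)
            site = CandidateSite(contig=contig, anchor_interval=(lo, hi))
            for e in group:
                (site.clipped_left if e.clip_side == "right"
                 else site.clipped_right).append(e)
            sites.append(site)

    for ev in by_bp:
        if group and breakpoint_of(ev) - breakpoint_of(group[-1]) > 2 * MIN_CLIP_LEN:
            flush(group)
            group = []
        group.append(ev)
    flush(group)

    sites.sort(key=lambda s: s.anchor_interval)
    return sites
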