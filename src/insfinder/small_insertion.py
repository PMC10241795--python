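"""Consensus-overlap detection of short insertions.

Insertions much shorter than the library insert size produce few or no
discordant pairs; their footprint is almost entirely soft-clipped reads
at the two junctions (which, for a pure insertion, are the same
reference coordinate).  Tails of reads clipped at the left junction
carry a prefix of the inserted sequence; tails clipped at the right
junction carry a suffix.  Each junction's tails are collapsed into a
majority-vote consensus and the two consensuses are merged by their
sequence overlap, reconstructing the full inserted sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core_io import DEFAULT_MIN_INSERTION_SIZE
from .evidence import MIN_CLIP_LEN, MIN_CLIPPED, EvidenceRead
from .finalize import AltAllele

BREAKPOINT_GROUP_TOL = 5
MAX_BP_GAP = 10
MIN_CO_OVERLAP = 10
MAX_CO_MISMATCHES = 1
CONSENSUS_MIN_AGREEMENT = 0.70


@dataclass(frozen=True)
class ClipConsensus:
    """Majority-vote consensus of clip tails sharing a breakpoint.

    ``side`` is the soft-clip side of the member reads: 'right' means
    the reads are anchored on the left flank and the tail extends
    rightward into the insertion from the left junction; 'left' is the
    mirror case at the right junction.  ``anchor_consensus`` is the
    consensus of the anchored (reference-matching) read portions.
    """

    contig: str
    breakpoint: int  # 0-based reference coordinate of the junction
    side: str
    anchor_consensus: str
    clip_consensus: str
    depth: int


def _column_consensus(columns: list[Counter],
                      min_agreement: float) -> str:
    """Consensus string, truncated at the first ambiguous column.

    A column is accepted when the leading base gathers >=
    ``min_agreement`` of the votes, or when at most one read dissents
    (so a single sequencing error cannot truncate a low-depth
    consensus).
    """
    out = []
    for votes in columns:
        if not votes:
            break
        base, n = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        total = sum(votes.values())
        if n < min_agreement * total and total - n > 1:
            break
        out.append(base)
    return "".join(out)


def build_clip_consensus(clipped: list[EvidenceRead], side: str,
                         min_clipped: int = MIN_CLIPPED,
                         min_clip_len: int = MIN_CLIP_LEN,
                         ) -> list[ClipConsensus]:
    """Group same-side clipped reads by breakpoint and build consensuses.

    Reads whose clip breakpoints lie within ``BREAKPOINT_GROUP_TOL`` of
    each other are grouped; tails are stacked aligned at each read's own
    breakpoint and a per-column majority vote (>= 70% agreement, else
    the consensus is truncated there) forms the clip consensus.  Groups
    with fewer than ``min_clipped`` reads, or whose consensus is shorter
    than ``min_clip_len``, are dropped.
    """
    reads = [e for e in clipped if e.role == "clipped" and e.clip_side == side]
    if not reads:
        return []
    contigs = {e.contig for e in reads}
    if len(contigs) > 1:
        raise ValueError("clipped reads must share a contig")
    contig = contigs.pop()

    def breakpoint_of(ev: EvidenceRead) -> int:
        return ev.end if side == "right" else ev.start

    reads.sort(key=lambda e: (breakpoint_of(e), e.read_id))
    groups: list[list[EvidenceRead]] = []
    for ev in reads:
        if groups and breakpoint_of(ev) - breakpoint_of(groups[-1][-1]) \
                <= BREAKPOINT_GROUP_TOL:
            groups[-1].append(ev)
        else:
            groups.append([ev])

    out: list[ClipConsensus] = []
    for group in groups:
        if len(group) < min_clipped:
            continue
        bps = sorted(breakpoint_of(e) for e in group)
        breakpoint = bps[len(bps) // 2]
        clip_cols: list[Counter] = []
        anchor_cols: list[Counter] = []
        for ev in group:
            # clip tails are aligned at the breakpoint: for a right clip
            # the tail reads away from it; for a left clip, toward it
            tail = ev.clip_seq if side == "right" else ev.clip_seq[::-1]
            for i, base in enumerate(tail):
                if i >= len(clip_cols):
                    clip_cols.append(Counter())
                clip_cols[i][base] += 1
            anchor = ev.anchor_seq[::-1] if side == "right" else ev.anchor_seq
            for i, base in enumerate(anchor):
                if i >= len(anchor_cols):
                    anchor_cols.append(Counter())
                anchor_cols[i][base] += 1
        clip_consensus = _column_consensus(clip_cols, CONSENSUS_MIN_AGREEMENT)
        anchor_consensus = _column_consensus(anchor_cols,
                                             CONSENSUS_MIN_AGREEMENT)
        if side == "left":
            clip_consensus = clip_consensus[::-1]
        if side == "right":
            anchor_consensus = anchor_consensus[::-1]
        if len(clip_consensus) < min_clip_len:
            continue
        out.append(ClipConsensus(
            contig=contig, breakpoint=breakpoint, side=side,
            anchor_consensus=anchor_consensus,
            clip_consensus=clip_consensus, depth=len(group)))
    return out


def overlap_call(left: ClipConsensus, right: ClipConsensus,
                 min_insertion_size: int = DEFAULT_MIN_INSERTION_SIZE,
                 max_bp_gap: int = MAX_BP_GAP,
                 min_co_overlap: int = MIN_CO_OVERLAP) -> AltAllele | None:
    """Merge the two junction consensuses into a complete inserted sequence.

    ``left`` must be the right-clipped consensus (tail = prefix of the
    inserted sequence, read from the left junction) and ``right`` the
    left-clipped one (tail ends at the right junction).  The best
    placement of ``right`` against ``left`` with an overlap of >=
    ``min_co_overlap`` and at most one mismatch is found; reads that
    span the whole insertion make either consensus overrun into flank
    sequence, so the inserted sequence is the merged span from the left
    junction (start of ``left``) to the right junction (end of
    ``right``).  Returns None when the junctions are too far apart, no
    acceptable overlap exists, or the merged length is below the
    minimum insertion size.
    """
    if left.side != "right" or right.side != "left":
        raise ValueError("expected a right-clipped and a left-clipped "
                         "consensus, in that order")
    if left.contig != right.contig:
        return None
    if abs(left.breakpoint - right.breakpoint) > max_bp_gap:
        return None
    L, R = left.clip_consensus, right.clip_consensus
    valid: list[tuple[int, int]] = []  # (overlap_len, offset)
    # offset = position of R's first base in L's frame (L starts at the
    # left junction); may be negative when R carries left-flank bases
    for offset in range(-len(R) + min_co_overlap,
                        len(L) - min_co_overlap + 1):
        lo = max(0, offset)
        hi = min(len(L), offset + len(R))
        if hi - lo < min_co_overlap:
            continue
        mism = sum(1 for i in range(lo, hi) if L[i] != R[i - offset])
        if mism > MAX_CO_MISMATCHES:
            continue
        valid.append((hi - lo, offset))
    if not valid:
        return None
    if len({off for _, off in valid}) > 1:
        # several placements are consistent with the data — typical of a
        # repeat expansion larger than the read span, where the inserted
        # length is not determined by sequence evidence.  Report the two
        # junction consensuses as an incomplete allele instead of
        # guessing a length.
        return AltAllele(
            contig=left.contig,
            left_flank=left.anchor_consensus,
            right_flank=right.anchor_consensus,
            left_flank_end=left.breakpoint,
            right_flank_start=right.breakpoint,
            complete=False, ins_prefix=L, ins_suffix=R, origin="clip",
            support_left=left.depth, support_right=right.depth)
    _, offset = max(valid)
    ins_len = offset + len(R)  # right junction in L's frame
    if ins_len < min_insertion_size:
        return None
    merged = []
    for i in range(ins_len):
        if 0 <= i < len(L):
            merged.append(L[i])
        else:
            merged.append(R[i - offset])
    inserted = "".join(merged)
    return AltAllele(
        contig=left.contig,
        left_flank=left.anchor_consensus,
        right_flank=right.anchor_consensus,
        left_flank_end=left.breakpoint,
        right_flank_start=right.breakpoint,
        complete=True, inserted=inserted, origin="clip",
        support_left=left.depth, support_right=right.depth)
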