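"""Strand-aware greedy overlap assembly of novel inserted sequences.

For insertions absent from the reference, the only sequence evidence is
the unstable mates and the clipped tails themselves.  Reads are first
oriented into a common insertion-forward frame and split into two
pools: the *left pool* (mates of forward-strand stable reads and
left-junction clip tails, which read into the insertion from its start)
and the *right pool* (mates of reverse-strand stable reads and
right-junction clip tails, which read out of it toward its end).  A
left contig is extended rightward only with left-pool reads and a right
contig leftward only with right-pool reads; this pool exclusivity is
what prunes chimeric extensions that positional clustering alone would
admit.  When the two contigs overlap, the insertion is fully assembled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._align import local_align_blocks, make_local_aligner
from .evidence import CandidateSite
from .finalize import AltAllele

MIN_OVERLAP = 20
MAX_MISMATCH_RATE = 0.05

_POLISH_ALIGNER = make_local_aligner(match=1, mismatch=-2, gap_open=-4)


@dataclass
class Contig:
    """An assembled contig with its layout provenance."""

    seq: str
    read_count: int
    anchored: str = "none"  # 'left', 'right', 'both', 'none'
    per_base_support: list[int] = field(default_factory=list)


def orient_reads(site: CandidateSite) -> tuple[list[str], list[str]]:
    """Split a site's sequence evidence into insertion-forward pools.

    Left pool: unstable mates of forward-strand stable reads
    (reverse-complemented from their as-sequenced orientation into the
    insertion-forward frame) plus right-soft-clipped tails.  Right pool:
    unstable mates of reverse-strand stable reads plus left-soft-clipped
    tails.  All returned strings read 5'->3' along the inserted
    sequence.
    """
    left_unstable, right_unstable = site.unstable_sequences()
    left_pool = left_unstable + [e.clip_seq for e in site.clipped_left]
    right_pool = right_unstable + [e.clip_seq for e in site.clipped_right]
    return left_pool, right_pool


def _overlap_len(a: str, b: str, min_overlap: int,
                 max_mismatch_rate: float) -> int:
    """Longest suffix(a)/prefix(b) overlap within the mismatch budget."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        budget = int(k * max_mismatch_rate)
        mism = 0
        sa, sb = a[-k:], b[:k]
        for x, y in zip(sa, sb):
            if x != y:
                mism += 1
                if mism > budget:
                    break
        else:
            return k
    return 0


def _valid_overlaps(a: str, b: str, min_overlap: int,
                    max_mismatch_rate: float) -> list[int]:
    """All suffix(a)/prefix(b) overlap lengths within the mismatch budget."""
    out = []
    for k in range(min_overlap, min(len(a), len(b)) + 1):
        budget = int(k * max_mismatch_rate)
        mism = 0
        for x, y in zip(a[-k:], b[:k]):
            if x != y:
                mism += 1
                if mism > budget:
                    break
        else:
            out.append(k)
    return out


def _polish(seq: str, reads: list[str]) -> str:
    """Column-majority consensus of the pool reads over an assembled contig.

    Greedy layout takes each extension verbatim from a single read, so a
    sequencing error in that read would survive; re-aligning every pool
    read and voting per column (>= 2 reads and >= 70% agreement to
    overturn a base) corrects such errors without changing the contig
    length.
    """
    votes: list[Counter] = [Counter() for _ in seq]
    for read in reads:
        res = local_align_blocks(read, seq, _POLISH_ALIGNER)
        if res is None:
            continue
        hit, blocks = res
        if hit.identity < 0.8 or hit.query_coverage(len(read)) < 0.5:
            continue
        for t0, t1, q0, q1 in blocks:
            for t, q in zip(range(t0, t1), range(q0, q1)):
                votes[t][read[q]] += 1
    out = list(seq)
    for i, v in enumerate(votes):
        if not v:
            continue
        base, n = max(v.items(), key=lambda kv: (kv[1], kv[0]))
        if base != out[i] and n >= 2 and n >= 0.7 * sum(v.values()):
            out[i] = base
    return "".join(out)


def _greedy_extend(seed: str, pool: list[str], direction: str,
                   min_overlap: int, max_mismatch_rate: float
                   ) -> tuple[str, int, list[int]]:
    """Greedily extend ``seed`` using reads from one pool only.

    ``direction`` 'right' extends the contig's 3' end with reads whose
    prefix overlaps its suffix; 'left' is the mirror case.  Ties in
    overlap length are broken by lexicographically smallest read, then
    input order, so assembly is deterministic.
    """
    contig = seed
    support = [1] * len(seed)
    used = [False] * len(pool)
    reads = sorted(range(len(pool)), key=lambda i: (pool[i], i))
    n_used = 0
    while True:
        best = None  # (overlap, read_key)
        for i in reads:
            if used[i]:
                continue
            read = pool[i]
            if direction == "right":
                ov = _overlap_len(contig, read, min_overlap, max_mismatch_rate)
                extension = len(read) - ov
            else:
                ov = _overlap_len(read, contig, min_overlap, max_mismatch_rate)
                extension = len(read) - ov
            if ov == 0 or extension <= 0:
                if ov > 0:
                    used[i] = True  # contained read: supports, no extension
                    n_used += 1
                    if direction == "right":
                        lo = len(contig) - ov
                        for j in range(lo, len(contig)):
                            support[j] += 1
                    else:
                        for j in range(ov):
                            support[j] += 1
                continue
            if best is None or ov > best[0]:
                best = (ov, i)
        if best is None:
            return contig, 1 + n_used, support
        ov, i = best
        used[i] = True
        n_used += 1
        read = pool[i]
        if direction == "right":
            for j in range(len(contig) - ov, len(contig)):
                support[j] += 1
            contig = contig + read[ov:]
            support.extend([1] * (len(read) - ov))
        else:
            for j in range(ov):
                support[j] += 1
            contig = read[:len(read) - ov] + contig
            support = [1] * (len(read) - ov) + support


def assemble(left_pool: list[str], right_pool: list[str],
             left_seed: str | None = None, right_seed: str | None = None,
             min_overlap: int = MIN_OVERLAP,
             max_mismatch_rate: float = MAX_MISMATCH_RATE
             ) -> AltAllele | None:
    """Assemble the inserted sequence from the two oriented pools.

    The left contig grows rightward from the left-junction clip
    consensus (or, failing that, the left-pool read with the most
    overlaps); the right contig grows leftward symmetrically.  A read
    from the opposite pool is never recruited.  If the contigs share an
    overlap of >= ``min_overlap`` they merge into a complete inserted
    sequence; otherwise a prefix/suffix allele is returned.  Flank
    fields of the returned allele are left empty for the caller to fill.
    """
    if not left_pool and not right_pool:
        return None

    def pick_seed(pool: list[str]) -> str | None:
        if not pool:
            return None
        if len(pool) == 1:
            return pool[0]
        best = None
        for i, cand in enumerate(sorted(pool)):
            n = sum(1 for other in pool if other is not cand and (
                _overlap_len(cand, other, min_overlap, max_mismatch_rate)
                or _overlap_len(other, cand, min_overlap, max_mismatch_rate)))
            if best is None or n > best[0]:
                best = (n, cand)
        return best[1]

    left_seed = left_seed or pick_seed(left_pool)
    right_seed = right_seed or pick_seed(right_pool)

    left_contig = None
    if left_seed:
        seq, n, sup = _greedy_extend(left_seed, left_pool, "right",
                                     min_overlap, max_mismatch_rate)
        left_contig = Contig(seq=seq, read_count=n, anchored="left",
                             per_base_support=sup)
    right_contig = None
    if right_seed:
        seq, n, sup = _greedy_extend(right_seed, right_pool, "left",
                                     min_overlap, max_mismatch_rate)
        right_contig = Contig(seq=seq, read_count=n, anchored="right",
                              per_base_support=sup)

    if left_contig and right_contig:
        overlaps = _valid_overlaps(left_contig.seq, right_contig.seq,
                                   min_overlap, max_mismatch_rate)
        merged = None
        if len(overlaps) == 1:
            ov = overlaps[0]
            if ov == len(right_contig.seq) or ov == len(left_contig.seq):
                # containment: one contig already spans the other
                merged = left_contig.seq if len(left_contig.seq) >= \
                    len(right_contig.seq) else right_contig.seq
            else:
                merged = left_contig.seq + right_contig.seq[ov:]
        # several consistent overlaps (a repeat longer than the read
        # span): the merged length is not determined by the data, so
        # fall through to an incomplete prefix/suffix allele
        if merged:
            merged = _polish(merged, left_pool + right_pool)
            return AltAllele(
                contig="", left_flank="", right_flank="",
                left_flank_end=0, right_flank_start=0, complete=True,
                inserted=merged, origin="denovo",
                support_left=left_contig.read_count,
                support_right=right_contig.read_count)
    if not (left_contig and right_contig):
        return None
    return AltAllele(
        contig="", left_flank="", right_flank="", left_flank_end=0,
        right_flank_start=0, complete=False,
        ins_prefix=left_contig.seq, ins_suffix=right_contig.seq,
        origin="denovo", support_left=left_contig.read_count,
        support_right=right_contig.read_count)
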