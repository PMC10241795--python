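"""Shared local-alignment and k-mer seeding helpers.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` that expose the
quantities the pipeline cares about (query/target spans, identity,
query coverage) plus a simple k-mer hit index used for genome-wide
remapping of unstable reads.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_local_aligner(match: float, mismatch: float, gap_open: float,
                       gap_extend: float | None = None) -> Align.PairwiseAligner:
    """Local (Smith-Waterman) aligner with linear or affine gaps.

    When ``gap_extend`` is omitted the extension penalty equals the
    opening penalty (linear gap cost).
    """
    if gap_extend is None:
        gap_extend = gap_open
    return Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query against a target."""

    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    mismatches: int
    aligned_columns: int

    @property
    def identity(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return self.matches / self.aligned_columns

    def query_coverage(self, query_length: int) -> float:
        if query_length == 0:
            return 1.0
        return (self.q_end - self.q_start) / query_length


def local_align(query: str, target: str, aligner: Align.PairwiseAligner) -> LocalHit | None:
    """Best local alignment, or None when no positive-scoring alignment exists."""
    if not query or not target:
        return None
    alignments = aligner.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    counts = aln.counts()
    return LocalHit(
        score=aln.score,
        q_start=int(q_blocks[0][0]),
        q_end=int(q_blocks[-1][1]),
        t_start=int(t_blocks[0][0]),
        t_end=int(t_blocks[-1][1]),
        matches=int(counts.identities),
        mismatches=int(counts.mismatches),
        aligned_columns=int(counts.identities + counts.mismatches),
    )


def local_align_blocks(query: str, target: str,
                       aligner: Align.PairwiseAligner
                       ) -> tuple[LocalHit, list[tuple[int, int, int, int]]] | None:
    """Best local alignment plus its gapless blocks.

    Blocks are (t_start, t_end, q_start, q_end) runs of aligned columns,
    suitable for per-column consensus voting.
    """
    if not query or not target:
        return None
    alignments = aligner.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    counts = aln.counts()
    hit = LocalHit(
        score=aln.score,
        q_start=int(q_blocks[0][0]),
        q_end=int(q_blocks[-1][1]),
        t_start=int(t_blocks[0][0]),
        t_end=int(t_blocks[-1][1]),
        matches=int(counts.identities),
        mismatches=int(counts.mismatches),
        aligned_columns=int(counts.identities + counts.mismatches),
    )
    blocks = [(int(tb[0]), int(tb[1]), int(qb[0]), int(qb[1]))
              for tb, qb in zip(t_blocks, q_blocks)]
    return hit, blocks


class KmerIndex:
    """Exact k-mer position index over a set of contigs.

    Used to seed genome-wide remapping of unstable mate sequences.  Only
    k-mers over {A,C,G,T} are indexed; highly repetitive k-mers (more
    than ``max_occ`` occurrences) are dropped to keep seeding specific.
    """

    def __init__(self, contigs: dict[str, str], k: int = 17, max_occ: int = 64):
        self.k = k
        self.max_occ = max_occ
        index: dict[str, list[tuple[str, int]]] = {}
        valid = set("ACGT")
        for name, seq in contigs.items():
            seq = seq.upper()
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i:i + k]
                if not valid.issuperset(kmer):
                    continue
                hits = index.setdefault(kmer, [])
                if len(hits) <= max_occ:
                    hits.append((name, i))
        # discard over-represented seeds
        self._index = {km: h for km, h in index.items() if len(h) <= max_occ}

    def seeds(self, seq: str, stride: int = 4) -> list[tuple[int, str, int]]:
        """(query_offset, contig, position) seed hits for ``seq``."""
        seq = seq.upper()
        out = []
        for off in range(0, max(1, len(seq) - self.k + 1), stride):
            for contig, pos in self._index.get(seq[off:off + self.k], ()):
                out.append((off, contig, pos))
        return out
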