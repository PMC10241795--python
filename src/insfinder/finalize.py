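"""Breakpoint refinement, filtering and call finalization.

The three allele-construction engines (reference-guided remap, de novo
assembly, clip-consensus overlap) all emit an :class:`AltAllele` — the
inserted sequence (possibly partial) flanked by reference sequence.
Here the alternative allele is re-anchored against the reference window
around the candidate site to fix the exact insertion point, converted
to a VCF-ready :class:`~insfinder.core_io.InsertionCall`, left-aligned,
and annotated with quality filters.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass

from ._align import make_local_aligner, local_align
from .core_io import (DEFAULT_MIN_INSERTION_SIZE, InsertionCall,
                      LibraryStats, fetch_reference, left_align_insertion,
                      reference_contigs)
from .evidence import CandidateSite

MIN_FLANK_IDENTITY = 0.9
MIN_FLANK_ALIGNED = 50
MAX_JUNCTION_DELTA = 15

_FLANK_ALIGNER = make_local_aligner(match=1, mismatch=-2, gap_open=-3)


@dataclass
class AltAllele:
    """Alternative-allele sequence: reference flanks around an insertion.

    ``left_flank`` ends at (0-based) reference coordinate
    ``left_flank_end``; ``right_flank`` starts at ``right_flank_start``
    (equal for a clean insertion).  Complete alleles carry ``inserted``;
    incomplete ones carry an assembled ``ins_prefix`` and ``ins_suffix``.
    """

    contig: str
    left_flank: str
    right_flank: str
    left_flank_end: int
    right_flank_start: int
    complete: bool
    inserted: str = ""
    ins_prefix: str = ""
    ins_suffix: str = ""
    support_left: int = 0
    support_right: int = 0
    origin: str = "denovo"  # 'remap' | 'denovo' | 'clip'

    def __post_init__(self):
        if self.complete and not self.inserted:
            raise ValueError("complete allele requires an inserted sequence")
        if not self.complete and not (self.ins_prefix or self.ins_suffix):
            raise ValueError("incomplete allele requires a prefix or suffix")


def _anchor_flank(flank: str, window: str, window_start: int,
                  junction_side: str) -> int | None:
    """Re-anchor one flank inside the reference window.

    Returns the 0-based reference coordinate of the junction (end of the
    left flank / start of the right flank), or None when the flank does
    not align with sufficient identity.
    """
    hit = local_align(flank, window, _FLANK_ALIGNER)
    if hit is None:
        return None
    min_aligned = min(MIN_FLANK_ALIGNED, len(flank))
    if hit.aligned_columns < min_aligned or hit.identity < MIN_FLANK_IDENTITY:
        return None
    if junction_side == "left":
        # junction is where the flank's last base lands; extrapolate over
        # any unaligned tail (ungapped assumption)
        return window_start + hit.t_end + (len(flank) - hit.q_end)
    return window_start + hit.t_start - hit.q_start


def refine_breakpoints(allele: AltAllele, site: CandidateSite, reference,
                       stats: LibraryStats,
                       min_insertion_size: int = DEFAULT_MIN_INSERTION_SIZE,
                       ) -> InsertionCall | None:
    """Remap the alternative allele to the reference to fix breakpoints.

    The two flanks are locally aligned inside the candidate window
    (anchor interval padded by two insert sizes).  Each flank must align
    with identity >= 0.9 over >= 50 bp, the two junctions must agree to
    within a small tolerance, and the resulting call is left-aligned.
    Returns None when the allele fails these gates.
    """
    contig_len = reference_contigs(reference)[allele.contig]
    pad = int(2 * stats.insert_mean)
    win_lo = max(0, site.anchor_interval[0] - pad)
    win_hi = min(contig_len, site.anchor_interval[1] + pad)
    window = fetch_reference(reference, allele.contig, win_lo, win_hi)

    jl = _anchor_flank(allele.left_flank, window, win_lo, "left")
    jr = _anchor_flank(allele.right_flank, window, win_lo, "right")
    if jl is None or jr is None:
        return None
    if not (win_lo <= jl <= win_hi):
        return None
    delta = jr - jl
    if abs(delta) > MAX_JUNCTION_DELTA:
        return None

    pos0 = jl  # number of reference bases before the insertion
    if pos0 < 1:
        return None

    if allele.complete:
        inserted = allele.inserted
        if delta > 0:
            # the right junction sits delta bases downstream: the start of
            # the inserted sequence re-aligns onto the reference gap
            gap_ref = fetch_reference(reference, allele.contig, jl, jr)
            if inserted.startswith(gap_ref):
                inserted = inserted[delta:]
                pos0 = jr
            else:
                return None
        if not inserted:
            return None
        call = InsertionCall(
            contig=allele.contig, pos=pos0, inserted_seq=inserted,
            complete=True, support_left=allele.support_left,
            support_right=allele.support_right)
        return left_align_insertion(call, reference)
    if not (allele.ins_prefix and allele.ins_suffix):
        return None
    return InsertionCall(
        contig=allele.contig, pos=pos0, complete=False,
        left_prefix=allele.ins_prefix, right_suffix=allele.ins_suffix,
        support_left=allele.support_left,
        support_right=allele.support_right)


_POLY_CG = re.compile(r"C{20,}|G{20,}")


def _in_regions(regions: dict[str, list[tuple[int, int]]],
                contig: str, pos0: int) -> bool:
    ivals = regions.get(contig)
    if not ivals:
        return False
    i = bisect.bisect_right(ivals, (pos0, float("inf"))) - 1
    return i >= 0 and ivals[i][0] <= pos0 < ivals[i][1]


def apply_filters(calls: list[InsertionCall], stats: LibraryStats,
                  exclude_regions: dict[str, list[tuple[int, int]]] | None = None,
                  min_insertion_size: int = DEFAULT_MIN_INSERTION_SIZE,
                  alignment_source=None,
                  hard_filter: bool = False) -> list[InsertionCall]:
    """Annotate calls with quality filters; optionally drop non-PASS calls.

    Filters: LOW_SUPPORT (combined support < 5 or one side empty),
    HIGH_DEPTH (local depth > 3x median; needs ``alignment_source``),
    POLY_CG (C/G homopolymer run of 20+ bp in a complete inserted
    sequence — a NovaSeq-style artefact signature), EXCLUDED_REGION
    (site inside a user-supplied BED region such as centromeres), SHORT
    (complete inserted sequence below the minimum size).  Annotation is
    recomputed from scratch, so the operation is idempotent and
    order-independent.
    """
    out = []
    for call in calls:
        filters: set[str] = set()
        total = call.support_left + call.support_right
        if total < 5 or call.support_left == 0 or call.support_right == 0:
            filters.add("LOW_SUPPORT")
        if alignment_source is not None and stats.median_depth > 0:
            depth = alignment_source.count(
                call.contig, max(0, call.pos - 50), call.pos + 50)
            local = depth * stats.read_length / (100 + stats.read_length)
            if local > 3 * stats.median_depth:
                filters.add("HIGH_DEPTH")
        if call.complete and _POLY_CG.search(call.inserted_seq):
            filters.add("POLY_CG")
        if exclude_regions and _in_regions(exclude_regions, call.contig,
                                           call.pos - 1):
            filters.add("EXCLUDED_REGION")
        if call.complete and call.svlen < min_insertion_size:
            filters.add("SHORT")
        call.filters = filters
        if hard_filter and filters:
            continue
        out.append(call)
    return out
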