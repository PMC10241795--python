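"""Domain types and I/O shared across the insertion-calling pipeline.

Covers library insert-size estimation (which defines what a discordant
pair is), insertion left-alignment, and VCF 4.2 emission/parsing.
Internally all coordinates are 0-based half-open; ``InsertionCall.pos``
is the 1-based position of the reference base immediately before the
inserted sequence, following VCF convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

DEFAULT_MIN_INSERTION_SIZE = 50


class ConfigurationError(RuntimeError):
    """Raised when the alignment source cannot support estimation."""


class InputError(ValueError):
    """Raised on malformed or inconsistent user inputs."""


# ---------------------------------------------------------------------------
# reference access helpers


def fetch_reference(reference, contig: str, start: int | None = None,
                    end: int | None = None) -> str:
    """Fetch reference sequence from a dict, pysam.FastaFile or pyfaidx.Fasta."""
    if isinstance(reference, dict):
        if contig not in reference:
            raise InputError(f"contig {contig!r} not present in reference")
        seq = reference[contig]
        return str(seq[slice(start, end)]).upper()
    if isinstance(reference, pysam.FastaFile):
        if contig not in reference.references:
            raise InputError(f"contig {contig!r} not present in reference")
        return reference.fetch(contig, start, end).upper()
    # pyfaidx.Fasta or anything mapping-like with __contains__/__getitem__
    if contig not in reference:
        raise InputError(f"contig {contig!r} not present in reference")
    return str(reference[contig][slice(start, end)]).upper()


def reference_contigs(reference) -> dict[str, int]:
    """Mapping of contig name -> length for any supported reference object."""
    if isinstance(reference, dict):
        return {name: len(seq) for name, seq in reference.items()}
    if isinstance(reference, pysam.FastaFile):
        return dict(zip(reference.references, reference.lengths))
    return {name: len(reference[name][:]) for name in reference.keys()}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LibraryStats:
    """Sequencing-library summary used to classify read pairs.

    A pair is concordant when its template length falls inside
    ``[min_concordant_insert, max_concordant_insert]`` (mean +/- 3 sd)
    and its orientation is forward-reverse.
    """

    read_length: int
    insert_mean: float
    insert_sd: float
    max_concordant_insert: int
    min_concordant_insert: int
    median_depth: float

    def __post_init__(self):
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be non-negative")
        if not (self.max_concordant_insert >= self.insert_mean
                >= self.min_concordant_insert >= 0):
            raise ValueError(
                "require max_concordant_insert >= insert_mean >= "
                "min_concordant_insert >= 0")


@dataclass
class InsertionCall:
    """A finalized, VCF-ready insertion.

    ``pos`` is 1-based and anchors the base immediately before the
    inserted sequence.  Complete calls carry the full ``inserted_seq``;
    incomplete calls carry a ``left_prefix``/``right_suffix`` of it and
    report ``svlen`` as a lower bound.
    """

    contig: str
    pos: int
    inserted_seq: str = ""
    left_prefix: str = ""
    right_suffix: str = ""
    complete: bool = True
    svlen: int = 0
    support_left: int = 0
    support_right: int = 0
    filters: set[str] = field(default_factory=set)
    sample_id: str = ""

    def __post_init__(self):
        if self.complete:
            if not self.inserted_seq:
                raise ValueError("complete call requires inserted_seq")
            self.svlen = len(self.inserted_seq)
        else:
            if not (self.left_prefix and self.right_suffix):
                raise ValueError(
                    "incomplete call requires left_prefix and right_suffix")
            if self.inserted_seq:
                raise ValueError("incomplete call cannot carry inserted_seq")
            self.svlen = max(self.svlen,
                             len(self.left_prefix) + len(self.right_suffix))
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


# ---------------------------------------------------------------------------
# library statistics


def estimate_library_stats(alignment_source, sample_size: int = 10000,
                           trim_fraction: float = 0.001) -> LibraryStats:
    """Estimate insert-size statistics from sampled proper pairs.

    Template lengths of up to ``sample_size`` proper pairs are collected
    from the start of the file; the top and bottom ``trim_fraction`` of
    values are discarded before computing moments (robustness against
    chimeric fragments).  Raises :class:`ConfigurationError` when fewer
    than min(1000, sample_size) proper pairs are found.
    """
    own = False
    if isinstance(alignment_source, str):
        alignment_source = pysam.AlignmentFile(alignment_source)
        own = True
    try:
        tlens: list[int] = []
        read_lengths: dict[int, int] = {}
        n_records = 0
        for read in alignment_source.fetch(until_eof=True):
            n_records += 1
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if read.query_length:
                read_lengths[read.query_length] = \
                    read_lengths.get(read.query_length, 0) + 1
            if read.is_proper_pair and read.template_length > 0:
                tlens.append(read.template_length)
                if len(tlens) >= sample_size:
                    break
        required = min(1000, sample_size)
        if len(tlens) < required:
            raise ConfigurationError(
                f"need at least {required} proper pairs to estimate library "
                f"statistics, found {len(tlens)}")
        arr = np.sort(np.asarray(tlens, dtype=float))
        trim = int(len(arr) * trim_fraction)
        if trim:
            arr = arr[trim:-trim]
        mean = float(arr.mean())
        sd = float(arr.std())
        read_length = max(read_lengths, key=read_lengths.get)
        depth = _estimate_median_depth(alignment_source, read_length)
        return LibraryStats(
            read_length=read_length,
            insert_mean=mean,
            insert_sd=sd,
            max_concordant_insert=math.ceil(mean + 3 * sd),
            min_concordant_insert=math.floor(max(0.0, mean - 3 * sd)),
            median_depth=depth,
        )
    finally:
        if own:
            alignment_source.close()


def _estimate_median_depth(alignment, read_length: int,
                           n_probes: int = 100) -> float:
    """Median read depth over evenly spaced probe positions."""
    if not alignment.has_index():
        return 0.0
    depths = []
    for contig, length in zip(alignment.references, alignment.lengths):
        step = max(1, length // max(1, n_probes // max(1, alignment.nreferences)))
        for pos in range(step // 2, length, step):
            depths.append(alignment.count(contig, pos, pos + 1))
    return float(np.median(depths)) if depths else 0.0


# ---------------------------------------------------------------------------
# left alignment


def left_align_insertion(call: InsertionCall, reference) -> InsertionCall:
    """Shift a complete insertion to its leftmost equivalent position.

    While the last base of the inserted sequence equals the reference
    base just before the insertion point, the insertion can be moved one
    base left with a right-rotation of its sequence without changing the
    alternate haplotype.  Idempotent; never increases ``pos``.
    """
    if not call.complete:
        raise InputError("left alignment requires a complete call")
    # 0-based insertion point: number of reference bases before the insertion
    j = call.pos
    window_start = max(0, j - len(call.inserted_seq) - 4096)
    ref = fetch_reference(reference, call.contig, window_start, j)
    seq = call.inserted_seq.upper()
    k = j
    offset = k - window_start
    while k > 1 and offset > 0 and seq[-1] == ref[offset - 1]:
        seq = seq[-1] + seq[:-1]
        k -= 1
        offset -= 1
    if k == call.pos:
        return call
    return replace(call, pos=k, inserted_seq=seq)


# ---------------------------------------------------------------------------
# VCF emission / parsing

_FILTER_DESCRIPTIONS = {
    "LOW_SUPPORT": "Fewer than the minimum supporting reads, or a two-sided "
                   "site with one empty side",
    "HIGH_DEPTH": "Local depth exceeds 3x the median library depth",
    "POLY_CG": "Inserted sequence contains a C or G homopolymer run of 20+ bp",
    "EXCLUDED_REGION": "Insertion site falls inside a user-excluded region",
    "SHORT": "Inserted sequence shorter than the minimum insertion size",
    "ONE_SIDED": "Supported by stable reads on one side only",
}


def _build_vcf_header(reference, sample_id: str | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in reference_contigs(reference).items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("SVLEN", 1, "Integer",
                    "Inserted sequence length (lower bound when INCOMPLETE)")
    header.info.add("SVINSSEQ_LEFT", 1, "String",
                    "Assembled prefix of the inserted sequence")
    header.info.add("SVINSSEQ_RIGHT", 1, "String",
                    "Assembled suffix of the inserted sequence")
    header.info.add("INCOMPLETE", 0, "Flag",
                    "Inserted sequence only partially assembled")
    header.info.add("SUPPORT_LEFT", 1, "Integer",
                    "Supporting reads on the left of the insertion site")
    header.info.add("SUPPORT_RIGHT", 1, "Integer",
                    "Supporting reads on the right of the insertion site")
    header.info.add("SAMPLE_ID", 1, "String", "Source sample identifier")
    header.info.add("END", 1, "Integer", "End position (equals POS for "
                    "insertions)")
    for name, desc in _FILTER_DESCRIPTIONS.items():
        header.filters.add(name, None, None, desc)
    return header


def write_vcf(calls: list[InsertionCall], reference, output_path: str) -> None:
    """Write calls (sorted by contig, pos) as a VCF 4.2 file."""
    lengths = reference_contigs(reference)
    order = {name: i for i, name in enumerate(lengths)}
    last = None
    for call in calls:
        if call.contig not in lengths:
            raise InputError(f"call contig {call.contig!r} not in reference")
        if call.pos > lengths[call.contig]:
            raise InputError(
                f"pos {call.pos} beyond contig {call.contig} "
                f"({lengths[call.contig]} bp)")
        key = (order[call.contig], call.pos)
        if last is not None and key < last:
            raise RuntimeError("calls must be sorted by (contig, pos)")
        last = key
    header = _build_vcf_header(reference)
    extra_filters = {f for c in calls for f in c.filters} - set(_FILTER_DESCRIPTIONS)
    for name in sorted(extra_filters):
        if name != "PASS":
            header.filters.add(name, None, None, "Pipeline filter")
    vcf = pysam.VariantFile(output_path, "w", header=header)
    try:
        for call in calls:
            ref_base = fetch_reference(reference, call.contig,
                                       call.pos - 1, call.pos)
            if call.complete:
                rec = vcf.new_record(
                    contig=call.contig, start=call.pos - 1,
                    alleles=(ref_base, ref_base + call.inserted_seq))
            else:
                rec = vcf.new_record(contig=call.contig, start=call.pos - 1,
                                     stop=call.pos, alleles=(ref_base, "<INS>"))
                rec.info["SVINSSEQ_LEFT"] = call.left_prefix
                rec.info["SVINSSEQ_RIGHT"] = call.right_suffix
                rec.info["INCOMPLETE"] = True
            rec.info["SVTYPE"] = "INS"
            rec.info["SVLEN"] = call.svlen
            rec.info["SUPPORT_LEFT"] = call.support_left
            rec.info["SUPPORT_RIGHT"] = call.support_right
            if call.sample_id:
                rec.info["SAMPLE_ID"] = call.sample_id
            if call.filters:
                for name in sorted(call.filters):
                    rec.filter.add(name)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)
    finally:
        vcf.close()


def read_vcf(path: str) -> list[InsertionCall]:
    """Parse insertions back from a VCF written by :func:`write_vcf`.

    Also tolerates foreign insertion VCFs: records with an explicit ALT
    longer than REF are treated as complete insertions.
    """
    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            if info.get("SVTYPE", "INS") != "INS":
                continue
            filters = {f for f in rec.filter.keys() if f != "PASS"}
            support_left = int(info.get("SUPPORT_LEFT", 0))
            support_right = int(info.get("SUPPORT_RIGHT", 0))
            sample_id = str(info.get("SAMPLE_ID", ""))
            alt = rec.alts[0] if rec.alts else "<INS>"
            if alt.startswith("<"):
                left = str(info.get("SVINSSEQ_LEFT", ""))
                right = str(info.get("SVINSSEQ_RIGHT", ""))
                svlen = info.get("SVLEN", 0)
                svlen = abs(int(svlen[0] if isinstance(svlen, tuple) else svlen))
                if not (left and right):
                    # foreign symbolic record without sequence: skip
                    continue
                calls.append(InsertionCall(
                    contig=rec.contig, pos=rec.pos, complete=False,
                    left_prefix=left, right_suffix=right, svlen=svlen,
                    support_left=support_left, support_right=support_right,
                    filters=filters, sample_id=sample_id))
            else:
                inserted = alt[len(rec.ref):]
                calls.append(InsertionCall(
                    contig=rec.contig, pos=rec.pos, inserted_seq=inserted,
                    complete=True, support_left=support_left,
                    support_right=support_right, filters=filters,
                    sample_id=sample_id))
    return calls


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file (0-based half-open) into per-contig interval lists."""
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{line_no}: BED line has < 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}:{line_no}: non-integer BED bounds") from exc
            if end < start:
                raise InputError(f"{path}:{line_no}: end < start")
            regions.setdefault(parts[0], []).append((start, end))
    for ivals in regions.values():
        ivals.sort()
    return regions
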