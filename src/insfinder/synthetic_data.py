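"""Synthetic genomes, planted insertions and paired-end reads.

Generates a random reference, plants insertions of every class the
caller targets (transpositions with optional divergence, novel
sequence, short insertions, STR expansions adjacent to a pre-planted
motif run, and tandem duplications), and simulates an FR paired-end
library over the alternate haplotype.  Reads are placed back onto
*reference* coordinates analytically, reproducing the evidence
signatures a mapper would emit: reads within flank sequence map
cleanly, junction-straddling reads are soft-clipped at the junction,
and reads sequenced entirely from an inserted sequence are emitted
unmapped at their anchored mate's position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from ._align import revcomp
from .core_io import InsertionCall, left_align_insertion, write_vcf

# a junction-straddling read is only considered mappable when its
# reference-consistent portion reaches this length (mapper seed size)
MIN_MAP_ANCHOR = 20

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised when the requested configuration cannot be realised."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults describe a desk-scale benchmark: a 1 Mb genome carrying
    100 insertions (30% diverged transpositions, 30% novel, 25% short,
    15% STR expansions) sequenced as 2x150 bp pairs with a 400 +/- 50 bp
    insert at 40x and 0.2% substitution error.
    """

    genome_length: int = 1_000_000
    gc: float = 0.42
    n_insertions: int = 100
    class_mix: dict = field(default_factory=lambda: {
        "transposition_diverged": 0.30,
        "novel": 0.30,
        "small": 0.25,
        "str_expansion": 0.15,
    })
    ins_size_range: tuple[int, int] = (100, 1500)
    small_size_range: tuple[int, int] = (50, 120)
    str_size_range: tuple[int, int] = (50, 150)
    divergence: float = 0.02
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    coverage: float = 40.0
    error_rate: float = 0.002
    seed: int = 1
    contig_name: str = "sim1"
    sample_id: str = "sim_sample"

    def __post_init__(self):
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("class_mix proportions must sum to 1")
        for lo, hi in (self.ins_size_range, self.small_size_range,
                       self.str_size_range):
            if lo < 50 or hi < lo:
                raise SimulationError(
                    "insertion size ranges must satisfy 50 <= min <= max")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """One planted insertion in canonical (left-aligned) form.

    ``pos`` counts the reference bases before the insertion (0-based
    insertion point; numerically equal to the 1-based VCF anchor-base
    position).
    """

    contig: str
    pos: int
    inserted_seq: str
    ins_class: str
    source_interval: tuple[int, int, str] | None = None
    sample_id: str = ""


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = (b"A", b"C", b"G", b"T")
    for i in hits:
        choices = [b for b in bases if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _class_counts(mix: dict, n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n insertions over classes."""
    items = sorted(mix.items())
    floors = {c: int(np.floor(p * n)) for c, p in items}
    rest = n - sum(floors.values())
    remainders = sorted(items, key=lambda cp: (-(cp[1] * n - np.floor(cp[1] * n)), cp[0]))
    for c, _ in remainders[:rest]:
        floors[c] += 1
    return floors


def make_truth(config: SimConfig
               ) -> tuple[dict[str, str], str, list[TruthRecord]]:
    """Build (reference, alternate haplotype, truth records).

    The reference is drawn i.i.d. at the configured GC.  Insertion loci
    are spaced at least two insert sizes apart.  Truth records are
    reported left-aligned so that exact comparisons against left-aligned
    calls are well defined.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    margin = int(4 * config.insert_mean)
    spacing = int(2 * config.insert_mean)
    n = config.n_insertions

    ref = _random_seq(rng, L, config.gc)

    if n > 0:
        slot = (L - 2 * margin) // n
        if slot < spacing + 200:
            raise SimulationError(
                f"cannot place {n} insertions >= {spacing} bp apart in a "
                f"{L} bp genome")
        jitter = rng.integers(0, slot - spacing, size=n)
        positions = [margin + i * slot + int(jitter[i]) for i in range(n)]
    else:
        positions = []

    counts = _class_counts(config.class_mix, n)
    classes: list[str] = []
    for cls in sorted(counts):
        classes.extend([cls] * counts[cls])
    rng.shuffle(classes)

    # STR loci need a motif run present in the reference itself
    ref_arr = list(ref)
    str_motifs: dict[int, str] = {}
    for pos, cls in zip(positions, classes):
        if cls != "str_expansion":
            continue
        mlen = int(rng.integers(2, 7))
        motif = _random_seq(rng, mlen, 0.5)
        copies_in_ref = max(4, int(np.ceil(24 / mlen)))
        run = motif * copies_in_ref
        ref_arr[pos - len(run):pos] = list(run)
        str_motifs[pos] = motif
    ref = "".join(ref_arr)

    records: list[TruthRecord] = []
    for pos, cls in zip(positions, classes):
        source = None
        if cls in ("transposition", "transposition_diverged"):
            size = int(rng.integers(config.ins_size_range[0],
                                    config.ins_size_range[1] + 1))
            while True:
                src = int(rng.integers(margin, L - margin - size))
                if all(abs(src - p) > 1000 and abs(src + size - p) > 1000
                       for p in positions):
                    break
            seg = ref[src:src + size]
            div = config.divergence if cls == "transposition_diverged" else 0.0
            seq = _mutate(rng, seg, div)
            orientation = "forward"
            if rng.random() < 0.5:
                seq = revcomp(seq)
                orientation = "reverse"
            source = (src, src + size, orientation)
        elif cls == "novel":
            size = int(rng.integers(config.ins_size_range[0],
                                    config.ins_size_range[1] + 1))
            seq = _random_seq(rng, size, config.gc)
        elif cls == "small":
            size = int(rng.integers(config.small_size_range[0],
                                    config.small_size_range[1] + 1))
            seq = _random_seq(rng, size, config.gc)
        elif cls == "str_expansion":
            motif = str_motifs[pos]
            lo, hi = config.str_size_range
            k = int(rng.integers(int(np.ceil(lo / len(motif))),
                                 hi // len(motif) + 1))
            seq = motif * k
        elif cls == "tandem_dup":
            size = int(rng.integers(config.ins_size_range[0],
                                    min(config.ins_size_range[1], pos) + 1))
            i = int(rng.integers(0, size + 1))
            # region R spans ref[pos-i : pos-i+size]; S = R[i+1..n]R[1..i]
            seq = ref[pos:pos + size - i] + ref[pos - i:pos]
        else:
            raise SimulationError(f"unknown insertion class {cls!r}")
        records.append(TruthRecord(
            contig=config.contig_name, pos=pos, inserted_seq=seq,
            ins_class=cls, source_interval=source,
            sample_id=config.sample_id))

    reference = {config.contig_name: ref}
    haplotype = _apply_insertions(ref, records)
    records = [_left_align_truth(rec, reference) for rec in records]
    return reference, haplotype, records


def _apply_insertions(ref: str, records: list[TruthRecord]) -> str:
    parts = []
    prev = 0
    for rec in sorted(records, key=lambda r: r.pos):
        parts.append(ref[prev:rec.pos])
        parts.append(rec.inserted_seq)
        prev = rec.pos
    parts.append(ref[prev:])
    return "".join(parts)


def _left_align_truth(rec: TruthRecord, reference: dict) -> TruthRecord:
    call = InsertionCall(contig=rec.contig, pos=rec.pos,
                         inserted_seq=rec.inserted_seq, complete=True)
    aligned = left_align_insertion(call, reference)
    return replace(rec, pos=aligned.pos, inserted_seq=aligned.inserted_seq)


def write_reference_fasta(reference: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(path)


def write_truth_vcf(records: list[TruthRecord], reference: dict,
                    path: str) -> None:
    calls = [InsertionCall(contig=r.contig, pos=r.pos,
                           inserted_seq=r.inserted_seq, complete=True,
                           sample_id=r.sample_id)
             for r in sorted(records, key=lambda r: (r.contig, r.pos))]
    write_vcf(calls, reference, path)


# ---------------------------------------------------------------------------
# read simulation


def _haplotype_blocks(ref_len: int, records: list[TruthRecord]
                      ) -> list[tuple[int, int, str, int]]:
    """(hap_start, hap_end, kind, ref_anchor) blocks of the haplotype.

    ``kind`` is 'ref' (ref_anchor = reference start of the block) or
    'ins' (ref_anchor = the insertion point on the reference).
    """
    blocks = []
    hap = 0
    prev = 0
    for rec in sorted(records, key=lambda r: r.pos):
        flank = rec.pos - prev
        blocks.append((hap, hap + flank, "ref", prev))
        hap += flank
        blocks.append((hap, hap + len(rec.inserted_seq), "ins", rec.pos))
        hap += len(rec.inserted_seq)
        prev = rec.pos
    blocks.append((hap, hap + ref_len - prev, "ref", prev))
    return blocks


def _map_read(blocks, s: int, e: int):
    """Analytically map haplotype interval [s, e) to the reference.

    Returns (ref_pos, cigar) for a mappable read or None for an
    unmapped one.  Soft clips arise at insertion junctions; the anchor
    is the longer reference-consistent portion and must reach
    MIN_MAP_ANCHOR bases.
    """
    touched = [b for b in blocks if b[0] < e and b[1] > s]
    ref_parts = [b for b in touched if b[2] == "ref"]
    if not ref_parts:
        return None
    # at most one insertion can be touched (loci are spaced >= 2 inserts)
    left = next((b for b in ref_parts if b[0] <= s), None)
    right = next((b for b in ref_parts if b[1] >= e), None)
    a = (left[1] - s) if left and left is not right else 0
    c = (e - right[0]) if right and right is not left else 0
    if left is not None and left is right:
        # read fully inside one reference block
        ref_pos = left[3] + (s - left[0])
        return ref_pos, f"{e - s}M"
    if max(a, c) < MIN_MAP_ANCHOR:
        return None
    if a >= c:
        ref_pos = left[3] + (s - left[0])
        return ref_pos, f"{a}M{e - s - a}S"
    ref_pos = right[3] + max(0, s - right[0])
    return ref_pos, f"{e - s - c}S{c}M"


def simulate_reads(reference: dict[str, str], haplotype: str,
                   records: list[TruthRecord], config: SimConfig,
                   out_prefix: str) -> str:
    """Simulate an FR paired-end library and write a sorted, indexed BAM.

    Fragments are sampled uniformly over the alternate haplotype with
    Normal(insert_mean, insert_sd) lengths until the target coverage is
    reached; each yields one forward and one reverse 150 bp read (first
    /second read assignment randomised).  Substitution errors are added
    at ``error_rate``.  Pairs in which neither read is mappable are
    dropped.  Returns the BAM path (``out_prefix + '.bam'``).
    """
    rng = np.random.default_rng(config.seed + 1)
    contig = config.contig_name
    ref_len = len(reference[contig])
    rl = config.read_length
    blocks = _haplotype_blocks(ref_len, records)
    hap_len = len(haplotype)
    n_frags = int(np.ceil(config.coverage * hap_len / (2 * rl)))

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": ref_len}],
              "RG": [{"ID": config.sample_id, "SM": config.sample_id}]}

    frag_lens = np.maximum(
        2 * rl, np.round(rng.normal(config.insert_mean, config.insert_sd,
                                    size=n_frags)).astype(int))
    frag_starts = rng.integers(0, np.maximum(1, hap_len - frag_lens))
    swap_flags = rng.random(n_frags) < 0.5

    sam_path = out_prefix + ".unsorted.sam"
    bam_path = out_prefix + ".bam"
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for i in range(n_frags):
            f, flen = int(frag_starts[i]), int(frag_lens[i])
            fwd_seq = haplotype[f:f + rl]
            rev_raw = revcomp(haplotype[f + flen - rl:f + flen])
            fwd_seq = _mutate(rng, fwd_seq, config.error_rate)
            rev_raw = _mutate(rng, rev_raw, config.error_rate)
            m_fwd = _map_read(blocks, f, f + rl)
            m_rev = _map_read(blocks, f + flen - rl, f + flen)
            if m_fwd is None and m_rev is None:
                continue
            name = f"sim{i}"
            r_fwd = pysam.AlignedSegment()
            r_fwd.query_name = name
            r_rev = pysam.AlignedSegment()
            r_rev.query_name = name
            for rec, mapping, is_rev, raw in (
                    (r_fwd, m_fwd, False, fwd_seq),
                    (r_rev, m_rev, True, rev_raw)):
                rec.is_paired = True
                if mapping is None:
                    rec.is_unmapped = True
                    rec.mapping_quality = 0
                    rec.query_sequence = raw  # as sequenced
                    rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
                else:
                    pos, cigar = mapping
                    rec.reference_id = 0
                    rec.reference_start = pos
                    rec.cigarstring = cigar
                    rec.mapping_quality = 60
                    rec.is_reverse = is_rev
                    # SEQ is stored reference-forward
                    rec.query_sequence = revcomp(raw) if is_rev else raw
                    rec.query_qualities = \
                        pysam.qualitystring_to_array("I" * rl)
            r_fwd.is_read1, r_rev.is_read2 = not swap_flags[i], not swap_flags[i]
            r_fwd.is_read2, r_rev.is_read1 = bool(swap_flags[i]), bool(swap_flags[i])
            for rec, mate in ((r_fwd, r_rev), (r_rev, r_fwd)):
                rec.mate_is_reverse = mate.is_reverse
                rec.mate_is_unmapped = mate.is_unmapped
                if mate.is_unmapped:
                    # unmapped mate is placed at this read's coordinate
                    rec.next_reference_id = rec.reference_id
                    rec.next_reference_start = rec.reference_start
                else:
                    rec.next_reference_id = 0
                    rec.next_reference_start = mate.reference_start
            if r_fwd.is_unmapped:
                r_fwd.reference_id = r_rev.reference_id
                r_fwd.reference_start = r_rev.reference_start
                r_fwd.next_reference_id = r_rev.reference_id
                r_fwd.next_reference_start = r_rev.reference_start
            if r_rev.is_unmapped:
                r_rev.reference_id = r_fwd.reference_id
                r_rev.reference_start = r_fwd.reference_start
                r_rev.next_reference_id = r_fwd.reference_id
                r_rev.next_reference_start = r_fwd.reference_start
            if not r_fwd.is_unmapped and not r_rev.is_unmapped:
                tl = (r_rev.reference_end - r_fwd.reference_start)
                r_fwd.template_length = tl
                r_rev.template_length = -tl
                # flag proper only for fragments free of inserted bases
                if tl == flen:
                    r_fwd.is_proper_pair = True
                    r_rev.is_proper_pair = True
            out.write(r_fwd)
            out.write(r_rev)
    pysam.sort("-o", bam_path, sam_path)
    os.unlink(sam_path)
    pysam.index(bam_path)
    return bam_path


def simulate_sample(config: SimConfig, out_dir: str
                    ) -> dict[str, str | list[TruthRecord]]:
    """Full simulation: reference FASTA, truth VCF and sorted BAM.

    Returns a dict with keys 'reference' (FASTA path), 'bam', 'truth_vcf'
    and 'truth' (the in-memory records).
    """
    os.makedirs(out_dir, exist_ok=True)
    reference, haplotype, records = make_truth(config)
    fasta = os.path.join(out_dir, "reference.fa")
    write_reference_fasta(reference, fasta)
    truth_vcf = os.path.join(out_dir, "truth.vcf")
    write_truth_vcf(records, reference, truth_vcf)
    bam = simulate_reads(reference, haplotype, records, config,
                         os.path.join(out_dir, "reads"))
    return {"reference": fasta, "bam": bam, "truth_vcf": truth_vcf,
            "truth": records}
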