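"""Strand-aware greedy overlap assembly."""

import pytest

from insfinder._align import revcomp
from insfinder.evidence import CandidateSite, EvidenceRead
from insfinder.novel_assembly import assemble, orient_reads

from conftest import random_seq


def tile_reads(seq, read_len, step, start=0, end=None):
    end = len(seq) if end is None else end
    return [seq[i:i + read_len]
            for i in range(start, end - read_len + 1, step)]


def make_site(left_mates_raw=(), right_mates_raw=(), clip_left=(),
              clip_right=()):
    """Site with unstable mates stored raw (as sequenced) and clip tails."""
    site = CandidateSite(contig="c", anchor_interval=(1000, 1010))
    for i, raw in enumerate(left_mates_raw):
        site.left_cluster.append(EvidenceRead(
            read_id=f"l{i}", contig="c", start=800, end=950, strand="+",
            role="stable", mapq=60, mate_seq=raw, mate_seq_is_raw=True))
    for i, raw in enumerate(right_mates_raw):
        site.right_cluster.append(EvidenceRead(
            read_id=f"r{i}", contig="c", start=1050, end=1200, strand="-",
            role="stable", mapq=60, mate_seq=raw, mate_seq_is_raw=True))
    for i, tail in enumerate(clip_left):
        site.clipped_left.append(EvidenceRead(
            read_id=f"cl{i}", contig="c", start=900, end=1000, strand="+",
            role="clipped", mapq=60, clip_side="right", clip_len=len(tail),
            clip_seq=tail, anchor_seq="A" * 50))
    for i, tail in enumerate(clip_right):
        site.clipped_right.append(EvidenceRead(
            read_id=f"cr{i}", contig="c", start=1000, end=1100, strand="-",
            role="clipped", mapq=60, clip_side="left", clip_len=len(tail),
            clip_seq=tail, anchor_seq="C" * 50))
    return site


class TestOrientReads:
    def test_left_mates_are_reverse_complemented_once(self):
        insert_fragment = "ACGTTGCA" * 10
        site = make_site(left_mates_raw=[revcomp(insert_fragment)])
        left_pool, right_pool = orient_reads(site)
        assert left_pool == [insert_fragment]
        assert right_pool == []

    def test_right_mates_kept_as_sequenced(self):
        insert_fragment = "GGATCCAT" * 10
        site = make_site(right_mates_raw=[insert_fragment])
        left_pool, right_pool = orient_reads(site)
        assert right_pool == [insert_fragment]

    def test_clip_tails_join_matching_pools(self):
        site = make_site(clip_left=["A" * 30], clip_right=["C" * 30])
        left_pool, right_pool = orient_reads(site)
        assert left_pool == ["A" * 30]
        assert right_pool == ["C" * 30]

    def test_pool_reads_are_substrings_of_truth_haplotype(self, rng):
        ins = random_seq(rng, 200)
        mates = tile_reads(ins, 100, 25)
        site = make_site(left_mates_raw=[revcomp(m) for m in mates])
        left_pool, _ = orient_reads(site)
        assert left_pool
        for read in left_pool:
            assert read in ins


class TestAssemble:
    def test_error_free_300bp_insertion_assembles_exactly(self, rng):
        ins = random_seq(rng, 300)
        left_pool = tile_reads(ins, 150, 10, end=270)
        right_pool = tile_reads(ins, 150, 10, start=30)
        allele = assemble(left_pool, right_pool,
                          left_seed=ins[:60], right_seed=ins[-60:])
        assert allele is not None
        assert allele.complete
        assert allele.inserted == ins

    def test_geometry_forces_incomplete_for_long_insertion(self, rng):
        ins = random_seq(rng, 2000)
        # pools only reach ~400 bp in from each junction (400 bp library)
        left_pool = tile_reads(ins, 150, 25, end=400)
        right_pool = tile_reads(ins, 150, 25, start=1600)
        allele = assemble(left_pool, right_pool,
                          left_seed=ins[:60], right_seed=ins[-60:])
        assert allele is not None
        assert not allele.complete
        assert ins.startswith(allele.ins_prefix[:100])
        assert ins.endswith(allele.ins_suffix[-100:])

    def test_pool_exclusivity_prevents_chimeric_contigs(self, rng):
        ins_a = random_seq(rng, 300)
        ins_b = random_seq(rng, 300)
        # left pool deliberately polluted with reads from a second event
        left_pool = tile_reads(ins_a, 150, 30, end=250) \
            + tile_reads(ins_b, 150, 30)
        right_pool = tile_reads(ins_a, 150, 30, start=50)
        allele = assemble(left_pool, right_pool,
                          left_seed=ins_a[:60], right_seed=ins_a[-60:])
        if allele is not None and allele.complete:
            # whatever was assembled must be a substring of exactly one
            # truth haplotype, never a chimera of both
            assert (allele.inserted in ins_a) != (allele.inserted in ins_b)

    def test_deterministic_under_pool_permutation(self, rng):
        ins = random_seq(rng, 250)
        left_pool = tile_reads(ins, 120, 15, end=220)
        right_pool = tile_reads(ins, 120, 15, start=40)
        a1 = assemble(left_pool, right_pool)
        a2 = assemble(list(reversed(left_pool)), list(reversed(right_pool)))
        assert a1 is not None and a2 is not None
        assert a1.complete == a2.complete
        assert a1.inserted == a2.inserted

    def test_single_base_read_error_corrected_by_polish(self, rng):
        ins = random_seq(rng, 300)
        left_pool = tile_reads(ins, 150, 10, end=270)
        # corrupt one base in the middle of one read
        bad = list(left_pool[5])
        bad[75] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[75]]
        left_pool[5] = "".join(bad)
        right_pool = tile_reads(ins, 150, 10, start=30)
        allele = assemble(left_pool, right_pool,
                          left_seed=ins[:60], right_seed=ins[-60:])
        assert allele is not None and allele.complete
        assert allele.inserted == ins

    def test_repeat_expansion_is_reported_incomplete(self):
        # a pure dinucleotide repeat longer than any read: the overlap
        # between the two contigs is ambiguous, so no length is guessed
        ins = "TG" * 150
        left_pool = tile_reads(ins, 100, 20, end=200)
        right_pool = tile_reads(ins, 100, 20, start=100)
        allele = assemble(left_pool, right_pool,
                          left_seed=ins[:60], right_seed=ins[-60:])
        assert allele is None or not allele.complete

    def test_empty_pools_give_none(self):
        assert assemble([], []) is None
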