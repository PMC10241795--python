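"""Benchmark toolkit: duplication exclusion, matching, classification."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from insfinder.core_io import InputError, InsertionCall
from insfinder.benchmark_tools import (TandemDupQuery,
                                       classify_inserted_sequence,
                                       cluster_population, evaluate,
                                       is_tandem_duplication,
                                       match_insertions,
                                       read_annotation_table,
                                       shortest_base_sequence, te_identify)
from insfinder._align import revcomp

from conftest import random_seq
from oracles import (shortest_base_bruteforce, sw_score,
                     tandem_dup_bruteforce)


class TestShortestBaseSequence:
    def test_period_60_returns_unit(self, rng):
        unit = random_seq(rng, 60)
        S = (unit * 5)[:300]
        assert shortest_base_sequence(S) == unit

    def test_aperiodic_returns_self(self, rng):
        S = random_seq(rng, 100)
        assert shortest_base_sequence(S) == S

    def test_short_period_rounds_up_to_min_len(self, rng):
        unit = random_seq(rng, 30)
        S = unit * 10
        # the smallest period >= 50 is the 60 bp double unit
        assert shortest_base_sequence(S) == unit * 2

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_bruteforce_on_random_periodicity(self, trial, rng):
        plen = int(rng.integers(5, 80))
        unit = random_seq(rng, plen)
        total = int(rng.integers(60, 300))
        S = (unit * (total // plen + 1))[:total]
        assert shortest_base_sequence(S) == shortest_base_bruteforce(S)

    def test_too_short_raises(self):
        with pytest.raises(InputError):
            shortest_base_sequence("ACGT" * 10)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(unit=st.text(alphabet="ACGT", min_size=1, max_size=60),
           copies=st.integers(1, 8), extra=st.integers(0, 59))
    def test_base_always_tiles_its_input(self, unit, copies, extra):
        S = unit * copies + unit[:min(extra, len(unit))]
        assume(len(S) >= 50)
        B = shortest_base_sequence(S)
        assert len(B) >= 50
        assert S == (B * (len(S) // len(B) + 1))[:len(S)]


class TestTandemDuplication:
    def test_exact_copy_of_left_flank_is_duplication(self, rng):
        ref = random_seq(rng, 2000)
        p = 1000
        S = ref[p - 60:p]  # i = n split
        q = TandemDupQuery(contig="c", p=p, S=S)
        assert is_tandem_duplication(q, {"c": ref})

    def test_rotation_split_is_duplication(self, rng):
        # S = R[i+1..n] R[1..i] for an interior split
        ref = random_seq(rng, 2000)
        p, n, i = 1000, 80, 30
        S = ref[p:p + n - i] + ref[p - i:p]
        q = TandemDupQuery(contig="c", p=p, S=S)
        assert is_tandem_duplication(q, {"c": ref})

    def test_random_sequence_is_not_duplication(self, rng):
        ref = random_seq(rng, 2000)
        S = random_seq(rng, 120)
        q = TandemDupQuery(contig="c", p=1000, S=S)
        assert not is_tandem_duplication(q, {"c": ref})

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_bruteforce_oracle(self, trial, rng):
        ref = random_seq(rng, 1500)
        p = int(rng.integers(400, 1100))
        size = int(rng.integers(60, 200))
        if trial % 2:
            i = int(rng.integers(0, size + 1))
            S = ref[p:p + size - i] + ref[p - i:p]
        else:
            S = random_seq(rng, size)
        q = TandemDupQuery(contig="c", p=p, S=S)
        assert is_tandem_duplication(q, {"c": ref}) == \
            tandem_dup_bruteforce(ref, p, S)


class TestMatchInsertions:
    def c(self, pos, seq=None, contig="c"):
        if seq is None:
            return InsertionCall(contig=contig, pos=pos, complete=False,
                                 left_prefix="A" * 60, right_suffix="C" * 60)
        return InsertionCall(contig=contig, pos=pos, inserted_seq=seq)

    def test_distance_500_is_inclusive_boundary(self, rng):
        a, b = self.c(1000, "A" * 60), self.c(1500, "A" * 60)
        assert match_insertions(a, b, "relaxed").matched
        assert not match_insertions(self.c(1000, "A" * 60),
                                    self.c(1501, "A" * 60), "relaxed").matched

    def test_identical_sequences_match_strict(self, rng):
        s = random_seq(rng, 100)
        d = match_insertions(self.c(1000, s), self.c(1000, s), "strict")
        assert d.matched
        assert d.sw_score == 200

    def test_length_difference_501_fails_strict(self, rng):
        a = self.c(1000, random_seq(rng, 100))
        b = self.c(1000, random_seq(rng, 601))
        assert not match_insertions(a, b, "strict").matched

    def test_sw_boundary_score_counts_as_match(self):
        # best local alignment is the shared 50 A run: score 2*50 = 100,
        # exactly min(l1, l2) -- the inclusive strict boundary
        s1 = "A" * 100
        s2 = "A" * 50 + "C" * 50
        d = match_insertions(self.c(1000, s1), self.c(1000, s2), "strict")
        assert d.sw_score == 100
        assert d.matched

    def test_different_contigs_never_match(self):
        a = self.c(1000, "A" * 60, contig="c1")
        b = self.c(1000, "A" * 60, contig="c2")
        assert not match_insertions(a, b, "relaxed").matched

    def test_incomplete_call_rejected_under_strict(self):
        with pytest.raises(InputError):
            match_insertions(self.c(1000), self.c(1000, "A" * 60), "strict")

    @pytest.mark.parametrize("trial", range(50))
    def test_strict_implies_relaxed(self, trial, rng):
        a = self.c(int(rng.integers(1, 3000)), random_seq(rng, int(rng.integers(50, 300))))
        b = self.c(int(rng.integers(1, 3000)), random_seq(rng, int(rng.integers(50, 300))))
        strict = match_insertions(a, b, "strict")
        relaxed = match_insertions(a, b, "relaxed")
        if strict.matched:
            assert relaxed.matched

    def test_strict_score_matches_dp_oracle(self, rng):
        s1, s2 = random_seq(rng, 80), random_seq(rng, 90)
        d = match_insertions(self.c(1000, s1), self.c(1000, s2), "strict")
        assert d.sw_score == sw_score(s1, s2)


class TestEvaluate:
    def test_identical_sets_are_perfect(self, rng):
        calls = [InsertionCall(contig="c", pos=p, inserted_seq=random_seq(rng, 60))
                 for p in (100, 5000, 9000)]
        res = evaluate(calls, calls, criterion="relaxed")
        assert res["sensitivity"] == 1.0
        assert res["precision"] == 1.0

    def test_calls_shifted_600_count_nothing(self, rng):
        truth = [InsertionCall(contig="c", pos=p, inserted_seq="A" * 60)
                 for p in (2000, 8000)]
        calls = [InsertionCall(contig="c", pos=p + 600, inserted_seq="A" * 60)
                 for p in (2000, 8000)]
        res = evaluate(calls, truth)
        assert res["sensitivity"] == 0.0
        assert res["precision"] == 0.0

    def test_hand_counted_tier_fixture(self, rng):
        truth = [InsertionCall(contig="c", pos=1000 * (i + 1),
                               inserted_seq="A" * 60) for i in range(10)]
        # 7 calls near distinct truths, 1 call far away but outside tier
        calls = [InsertionCall(contig="c", pos=1000 * (i + 1) + 100,
                               inserted_seq="A" * 60) for i in range(7)]
        calls.append(InsertionCall(contig="c", pos=50_000,
                                   inserted_seq="A" * 60))
        tier = {"c": [(0, 20_000)]}
        res = evaluate(calls, truth, tier_regions=tier)
        assert res["sensitivity"] == pytest.approx(0.7)
        assert res["precision"] == pytest.approx(1.0)
        assert res["n_calls_in_tier"] == 7


class TestClassify:
    def test_full_sine_annotation(self):
        assert classify_inserted_sequence([(0, 300, "SINE")], 300) == "SINE"

    def test_50bp_tolerance(self):
        assert classify_inserted_sequence([(0, 251, "SINE")], 300) == "SINE"
        assert classify_inserted_sequence([(0, 249, "SINE")], 300) == "other"

    def test_low_complexity_pools_simple_repeats(self):
        out = classify_inserted_sequence(
            [(0, 150, "Simple_repeat"), (150, 300, "Low_complexity")], 300)
        assert out == "low_complexity"

    def test_invariant_to_order_and_splitting(self, rng):
        base = [(0, 100, "LINE"), (100, 280, "LINE")]
        split = [(100, 280, "LINE"), (50, 100, "LINE"), (0, 50, "LINE")]
        assert classify_inserted_sequence(base, 300) == \
            classify_inserted_sequence(split, 300) == "LINE"

    def test_annotation_table_feeds_classifier(self, tmp_path):
        table = tmp_path / "rm.tsv"
        table.write_text("ins1\t0\t160\tSINE\nins1\t160\t300\tSINE\n"
                         "ins2\t0\t200\tSimple_repeat\n")
        anns = read_annotation_table(str(table))
        assert classify_inserted_sequence(anns["ins1"], 300) == "SINE"
        assert classify_inserted_sequence(anns["ins2"], 230) == \
            "low_complexity"


class TestTeIdentify:
    def test_exact_library_copy(self, rng):
        lib = {"Copia": random_seq(rng, 400), "Gypsy": random_seq(rng, 500)}
        assert te_identify(lib["Copia"], lib) == "Copia"

    def test_reverse_strand_copy(self, rng):
        lib = {"Copia": random_seq(rng, 400)}
        assert te_identify(revcomp(lib["Copia"]), lib) == "Copia"

    def test_random_sequence_is_none(self, rng):
        lib = {"Copia": random_seq(rng, 400)}
        assert te_identify(random_seq(rng, 300), lib) is None

    def test_15pct_divergent_copy_found(self, rng):
        lib = {"Copia": random_seq(rng, 400)}
        seq = list(lib["Copia"])
        idx = rng.choice(len(seq), size=60, replace=False)  # 15% subs
        for i in idx:
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        assert te_identify("".join(seq), lib) == "Copia"


class TestClusterPopulation:
    def call(self, pos, seq="A" * 60, sample="s1"):
        return InsertionCall(contig="c", pos=pos, inserted_seq=seq,
                             sample_id=sample)

    def test_diameter_80_single_cluster(self):
        clusters = cluster_population(
            [self.call(100), self.call(150, sample="s2"),
             self.call(180, sample="s3")])
        assert len(clusters) == 1

    def test_diameter_constraint_splits(self):
        clusters = cluster_population(
            [self.call(100), self.call(250, sample="s2"),
             self.call(400, sample="s3")])
        assert len(clusters) >= 2

    def test_representative_is_most_common(self):
        calls = [self.call(500, "G" * 70, f"s{i}") for i in range(3)]
        calls.append(self.call(530, "T" * 70, "s4"))
        clusters = cluster_population(calls)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.representative.pos == 500
        assert cl.representative.inserted_seq == "G" * 70
        assert cl.allele_count == 4

    def test_diameters_bounded_and_counts_conserved(self, rng):
        calls = [self.call(int(p), random_seq(rng, 55), f"s{i % 7}")
                 for i, p in enumerate(sorted(rng.integers(1, 50_000, size=200)))]
        clusters = cluster_population(calls)
        assert sum(len(c.calls) for c in clusters) == len(calls)
        for cl in clusters:
            lo, hi = cl.span
            assert hi - lo <= 200
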