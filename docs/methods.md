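# Methods

This note records the models, parameter choices and numerical decisions
behind `insfinder`, and what the simulation-based tests do and do not
demonstrate about real data.

## Library model and evidence definitions

Insert sizes are modelled as Normal(μ, σ²), estimated from the template
lengths of up to 10,000 proper pairs after discarding the top and
bottom 0.1% of values (robustness against chimeric fragments).  A pair
is *concordant* when both mates map in forward–reverse orientation with
template length inside [μ − 3σ, μ + 3σ]; anything else — mate unmapped,
inter-contig, same-strand, or out-of-range template — is discordant and
contributes a stable/unstable read pair.  Estimation refuses to run on
fewer than 1,000 proper pairs.  The 3σ convention is the standard
choice; it is not a fitted value.

Evidence gates: minimum mapping quality 20 for stable reads, minimum
soft-clip length 15 bp, PCR-duplicate and secondary/supplementary
records ignored.  Clustering is greedy single-linkage with a maximum
gap equal to the maximum concordant insert; a left (forward-strand) and
right (reverse-strand) cluster pair up when the right cluster starts
within [−read_length, max_insert] of the left cluster's end.  One-sided
clusters need ≥ 3 members; clip-only sites need ≥ 3 clipped reads.
These counts admit a 3-read consensus and are deliberately permissive —
precision is recovered later by the flank-identity gate and filters.

Unstable mate sequences are taken from mate-unmapped records placed at
the stable mate's coordinate (the convention used by standard mappers).
Mates mapped to *distant* loci are not individually fetched (random
access per read is prohibitively slow on large BAMs); on real data this
sacrifices some transposition evidence that the unmapped-mate and
clipped channels usually still provide.

## Allele construction

**Reference-guided remap.**  Unstable reads are seeded genome-wide with
a 17-mer index (seeds occurring > 64 times are dropped), hits are
clustered, and the top clusters are verified read-by-read with a local
aligner; a read supports a source when it aligns at ≥ 85% identity over
≥ 80% of its length.  A source needs ≥ 3 supporting reads; ties between
equally supported clusters go to the leftmost coordinate.  The source
sequence (reverse-complemented for reverse-orientation hits) is a
consensus backbone: a non-reference base is adopted at a column when
≥ 2 reads carrying it make up ≥ 70% of the column's coverage.  This is
what lets a diverged copy be reported with its true sequence rather
than the source's.  Indel divergence between copy and source is not
corrected — only substitutions are voted on — a known limitation.  The
allele is *complete* only when every column between the junction
anchors (located by clip tails ≥ 20 bp) is covered by ≥ 2 reads;
otherwise the read-covered prefix and suffix are reported.  Uncovered
interior sequence is never back-filled from the backbone, so a complete
sequence is always read-supported end to end.

**De novo assembly.**  Greedy overlap–layout–consensus with minimum
overlap 20 bp and mismatch rate ≤ 5%, chosen because per-site read
counts are tens, not millions.  The left contig is seeded by the
left-junction clip consensus (or the most-connected pool read) and may
only recruit left-pool reads; mirror-image for the right contig.  Ties
in overlap length break by lexicographically smallest read sequence,
then input order, making assembly deterministic.  After a merge, the
contig is *polished*: every pool read is realigned (≥ 80% identity over
≥ 50% of the read) and columns are re-voted, so a single-read
sequencing error inside an extension cannot survive.  When more than
one merge overlap is consistent with the data — the signature of a
repeat longer than the read span — no length is guessed and the allele
is emitted incomplete.

**Clip-consensus overlap.**  Same-side clipped reads whose breakpoints
lie within 5 bp are stacked at the breakpoint; a column is accepted
when the leading base has ≥ 70% of the votes or at most one read
dissents (the second clause keeps a single error from truncating a
depth-3 consensus).  The two junction consensuses are merged by the
longest placement with ≤ 1 mismatch over ≥ 10 overlapping bases.
Junction-spanning reads make each consensus overrun into flank
sequence, so the inserted sequence is taken as the span from the left
junction to the right junction inside the merged string, not the whole
merge.  Ambiguous placements (repeats) again yield an incomplete
allele.  Junctions more than 10 bp apart are not paired.

**Arbitration.**  Complete beats incomplete; then higher total support;
then remap > de novo > clip.  Calls within 10 bp after refinement are
deduplicated by the same ranking.

## Breakpoint refinement and filters

The allele's two flanks (2 × read_length of reference sequence) are
locally realigned inside the candidate window padded by 2μ.  Each flank
must align at ≥ 90% identity over ≥ 50 bp; the junctions must agree to
within 15 bp (a positive gap is accepted only when the inserted
sequence re-aligns onto it).  Calls are then left-aligned: while the
last inserted base equals the reference base preceding the insertion
point, shift left and rotate — giving the canonical leftmost
representation, idempotently.

Filters annotate rather than drop (use `--hard-filter` to drop):
`LOW_SUPPORT` (total support < 5 or either side 0), `HIGH_DEPTH`
(local depth > 3× median — collapsed-repeat signature), `POLY_CG`
(C or G homopolymer ≥ 20 bp in the inserted sequence, the NovaSeq
poly-G artefact signature), `EXCLUDED_REGION` (user BED, e.g.
centromeres — supplied as data, not hard-coded), `SHORT` (< 50 bp).
Thresholds are package choices; annotation is recomputed from scratch
on each invocation, so filtering is idempotent and order-independent.

## Benchmark toolkit

*Tandem-duplication exclusion.*  The base sequence B′ of an inserted
sequence S is the smallest multiple of S's fundamental period that
reaches 50 bp; the fundamental period (computed by failure function) is
trusted only when it fits at least twice, since any random sequence has
spurious "periods" of n−1, n−2 … from accidental short borders.  For
every split of B′, the suffix is aligned against the reference
immediately left of the insertion point and the prefix immediately
right (SW +1/−4/−6, linear gaps — the gap-extension cost is set equal
to opening and exposed as a parameter); ≥ 80% coverage of both pieces
marks a duplication.  A cheap ungapped pre-screen (≤ 25% mismatches)
skips splits that could not reach the coverage gate unless their
homology were indel-dominated; homology beyond that regime is declared
non-duplication, which is exact for the rotation-style duplications the
definition describes.

*Matching.*  Relaxed: insertion sites within 500 bp, inclusive, same
contig.  Strict adds |l₁ − l₂| ≤ 500 and SW(S₁, S₂; +2/−2/−4) ≥
min(l₁, l₂); incomplete calls are excluded from strict evaluation.
Evaluation counts per record — one truth record may be matched by many
calls and vice versa — and precision is computed only over calls inside
the confident ("tier") regions when supplied.

*Classification and TE assignment.*  A repeat class covers an inserted
sequence when its annotation intervals leave ≤ 50 bp uncovered;
low-complexity pools the low-complexity and simple-repeat annotation
classes; precedence SINE → LINE → low-complexity → other.  TE families
follow the 80-80 rule (≥ 80% identity, ≥ 80% coverage, both strands)
against a user-supplied library.

*Population clustering.*  Left-aligned calls are partitioned greedily
per contig so no cluster spans > 200 bp; the representative is the
(position, sequence) pair contributed by the most samples, ties to the
leftmost then lexicographically smallest.

## Simulator

The generator emits the study conditions used throughout the tests: a
1 Mb i.i.d. reference at GC 0.42 carrying 100 insertions — 30% diverged
transpositions (2% substitution divergence, random orientation,
100–1500 bp), 30% novel (100–1500 bp), 25% short (50–120 bp) and 15%
STR expansions — sequenced as 2×150 bp FR pairs, insert 400 ± 50 bp,
40× coverage, 0.2% substitution error, constant base quality.  STR
expansions insert whole copies of a 2–6 bp motif adjacent to a motif
run pre-planted in the reference (~24–30 bp), with total lengths of
50–150 bp: expansions detectable and sequence-resolvable from a 150 bp
read span, consistent with the intermediate-range expansions short
reads can recover.  Loci are spaced ≥ 2 inserts apart; truth records
are left-aligned so exact sequence comparison against left-aligned
calls is well defined.

Reads are placed on reference coordinates analytically rather than
through an external mapper, reproducing the evidence signatures
deterministically: flank reads map cleanly, junction-straddling reads
are soft-clipped at the junction (anchored on their longer
reference-consistent side when they span the whole event), and reads
whose reference-consistent portion is under 20 bp — a mapper's minimum
seed — are emitted unmapped at their anchored mate's position.  Pairs
with neither read mappable are dropped.  Proper-pair flags are set only
for fragments containing no inserted bases.

What the simulation does **not** model: mapping ambiguity and mapping
error (every analytic placement is correct), indel sequencing errors,
quality-score variation, PCR duplicates, reads from a transposition
aligning concordantly at the source locus, heterozygosity (the sample
is a homozygous alternate haplotype), and real repeat landscapes beyond
the planted runs.  Passing the end-to-end tests therefore demonstrates
the correctness of the algorithmic chain under clean mappings, not the
precision/recall to expect on real genomes, where alignment noise and
repeat structure dominate.

## Problem sizes and determinism

The end-to-end benchmarks run on a 1 Mb genome at 40× (~2.7 × 10⁵ read
pairs), where the full pipeline completes in about a minute on one CPU;
unit fixtures use 60–400 kb genomes.  All randomness flows from numpy
`default_rng` seeds carried in the configuration objects; identical
seeds give byte-identical references, BAMs and callsets, and the
acceptance script derives every internal seed from its `--seed`
argument.

## Known limitations

- Inserted-length recovery is bounded by fragment geometry: insertions
  longer than roughly 2μ − read_length assemble as prefix/suffix only.
- Repeat expansions whose total run exceeds the read span are reported
  incomplete by design; their length is not identifiable from sequence
  evidence at this read length.
- Guided consensus corrects substitutions but not indels relative to
  the source copy.
- No genotyping: calls carry support counts, not genotype likelihoods.
- Distant mapped unstable mates are not fetched (see evidence section).
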