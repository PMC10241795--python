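"""Shared fixtures: simulated samples, tiny alignment files, oracles."""

import numpy as np
import pysam
import pytest

from insfinder.synthetic_data import SimConfig, simulate_sample

BASES = np.array(list("ACGT"))


def random_seq(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 200 kb sample with 12 planted insertions of all default classes."""
    out_dir = tmp_path_factory.mktemp("smallsim")
    config = SimConfig(genome_length=200_000, n_insertions=12, seed=3)
    result = simulate_sample(config, str(out_dir))
    result["config"] = config
    return result


@pytest.fixture(scope="session")
def small_sim_reference(small_sim):
    return pysam.FastaFile(small_sim["reference"])


def make_bam(path, records, contigs=(("chr1", 100_000),)):
    """Write a coordinate-sorted, indexed BAM from record dicts."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": ln} for n, ln in contigs]}
    sam = str(path) + ".sam"
    with pysam.AlignmentFile(sam, "wh", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec["name"]
            a.query_sequence = rec.get("seq", "A" * rec.get("length", 100))
            a.flag = rec.get("flag", 0)
            a.reference_id = rec.get("tid", 0)
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec.get("cigar", f"{len(a.query_sequence)}M")
            a.next_reference_id = rec.get("mtid", rec.get("tid", 0))
            a.next_reference_start = rec.get("mpos", rec["pos"])
            a.template_length = rec.get("tlen", 0)
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(a.query_sequence))
            fh.write(a)
    bam = str(path)
    pysam.sort("-o", bam, sam)
    pysam.index(bam)
    return bam


def proper_pair_records(tlens, read_length=100, start=1000, gap=5):
    """Minimal proper-pair records with the given template lengths."""
    records = []
    for i, tlen in enumerate(tlens):
        pos = start + i * gap
        records.append({"name": f"p{i}", "pos": pos, "flag": 0x63,
                        "length": read_length, "tlen": int(tlen),
                        "mpos": pos + int(tlen) - read_length})
        records.append({"name": f"p{i}", "pos": pos + int(tlen) - read_length,
                        "flag": 0x93, "length": read_length,
                        "tlen": -int(tlen), "mpos": pos})
    return records
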