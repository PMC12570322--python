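import numpy as np
import pytest

from metaguide.io import Read
from metaguide.mapping import (AlignmentRecord, MapperParams, ReferenceIndex,
                               compute_coverage, map_reads, pileup, write_sam)
from metaguide.simdata import SimParams, simulate_reads

from conftest import random_seq
from oracles import interval_depth, revcomp


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(31)
    seq = random_seq(rng, 50_000)
    return seq, ReferenceIndex([("ref", seq)])


def test_exact_substring_maps_perfectly(reference):
    seq, idx = reference
    rec, = map_reads([Read("r", seq[1000:1250])], idx)
    assert (rec.ref_start, rec.ref_end, rec.identity, rec.strand) == \
        (1000, 1250, 1.0, "+")
    assert rec.cigar == [("M", 250)]
    rec, = map_reads([Read("r", revcomp(seq[2000:2250]))], idx)
    assert (rec.ref_start, rec.strand) == (2000, "-")
    assert rec.read_seq == seq[2000:2250]  # oriented to the reference


def test_random_and_bad_alphabet_reads_are_dropped(reference):
    _, idx = reference
    rng = np.random.default_rng(32)
    assert map_reads([Read("junk", random_seq(rng, 250))], idx) == []
    assert map_reads([Read("bad", "ACGT-RYKM" * 30)], idx) == []


def test_error_reads_map_to_true_locus(reference):
    """Reads at 1% substitution error map back to within 5 bp of their
    simulated origin at least 99% of the time."""
    seq, idx = reference
    reads, origins = simulate_reads([("ref", seq, 1.0)],
                                    SimParams(depth=5, error_rate=0.01, seed=33))
    recs = map_reads(reads, idx)
    assert len(recs) >= 0.99 * len(reads)
    good = sum(1 for r in recs if abs(r.ref_start - origins[r.read_id][1]) <= 5)
    assert good >= 0.99 * len(recs)


def test_determinism(reference):
    seq, idx = reference
    reads, _ = simulate_reads([("ref", seq, 1.0)],
                              SimParams(depth=1, error_rate=0.005, seed=34))
    a = map_reads(reads, idx)
    b = map_reads(reads, idx)
    assert [(r.read_id, r.ref_start, r.cigar, r.score) for r in a] == \
        [(r.read_id, r.ref_start, r.cigar, r.score) for r in b]


def test_no_gap_longer_than_max_gap(reference):
    """Gaps above half the read length are never embedded: the read is
    clipped to its best side instead."""
    seq, _ = reference
    rng = np.random.default_rng(35)
    read = Read("j", seq[24875:25125])
    for ins_len, spanned in [(100, True), (125, True), (250, False), (600, False)]:
        guide = seq[:25000] + random_seq(rng, ins_len) + seq[25000:]
        recs = map_reads([read], ("g", guide))
        assert recs, ins_len
        gaps = [l for op, l in recs[0].cigar if op in "ID"]
        assert all(g <= 125 for g in gaps)
        assert (max(gaps, default=0) == ins_len) == spanned


def _aln(rid, s, e, cigar=None, seq=""):
    return AlignmentRecord(rid, "ref", s, e, "+",
                           cigar or [("M", e - s)], 1.0, 8 * (e - s), seq)


def test_coverage_single_interval_and_abutment():
    cov = compute_coverage([_aln("a", 100, 350)], 1000)
    assert cov.depth[99] == 0 and cov.depth[100] == 1 and cov.depth[349] == 1
    assert cov.depth.sum() == 250
    cov = compute_coverage([_aln("a", 0, 250), _aln("b", 250, 500)], 500,
                           anchor_min=30)
    assert (cov.depth == 1).all()
    # nothing spans the junction: span depth is zero around position 250
    assert (cov.span_depth[220:280] == 0).all()
    assert cov.span_depth[100] == 1


def test_coverage_matches_bruteforce_counting():
    rng = np.random.default_rng(36)
    intervals = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 900, 60), rng.integers(1, 100, 60))]
    alns = [_aln(f"r{i}", s, e) for i, (s, e) in enumerate(intervals)]
    cov = compute_coverage(alns, 1000)
    assert np.array_equal(cov.depth, interval_depth(intervals, 1000))
    assert cov.depth.sum() == sum(e - s for s, e in intervals)


def test_coverage_bounds_check():
    with pytest.raises(ValueError, match="exceeds reference bounds"):
        compute_coverage([_aln("a", 990, 1010)], 1000)


def test_pileup_counts_and_depth_consistency():
    ref = "ACGTACGTAC" * 30
    reads = [Read(f"r{i}", ref[10:260]) for i in range(10)]
    alns = map_reads(reads, ("ref", ref))
    pile = pileup(alns, ("ref", ref))
    # ten identical error-free reads: count 10 for the reference base
    assert pile.base_counts[100, "ACGT".index(ref[100])] == 10
    assert pile.base_counts[100].sum() == 10

    # planted SNP split 7:3
    alt = "T" if ref[50] != "T" else "G"
    var = ref[:50] + alt + ref[51:]
    reads = [Read(f"v{i}", var[0:250]) for i in range(7)] + \
        [Read(f"w{i}", ref[0:250]) for i in range(3)]
    pile = pileup(map_reads(reads, ("ref", ref)), ("ref", ref))
    assert pile.base_counts[50, "ACGT".index(alt)] == 7
    assert pile.base_counts[50, "ACGT".index(ref[50])] == 3

    # pileup depth equals coverage depth on a random fixture
    rng = np.random.default_rng(37)
    seq = random_seq(rng, 3000)
    reads, _ = simulate_reads([("s", seq, 1.0)], SimParams(depth=8, seed=38))
    alns = map_reads(reads, ("s", seq))
    cov = compute_coverage(alns, len(seq))
    pile = pileup(alns, ("s", seq))
    assert np.array_equal(pile.depth, cov.depth)


def test_sam_export_is_valid(tmp_path):
    pysam = pytest.importorskip("pysam")
    rng = np.random.default_rng(39)
    seq = random_seq(rng, 2000)
    reads = [Read("a", seq[100:350]), Read("b", revcomp(seq[500:750]))]
    alns = map_reads(reads, ("ref", seq))
    path = tmp_path / "out.sam"
    write_sam(path, alns, ("ref", seq))
    with pysam.AlignmentFile(str(path), "r") as sam:
        recs = list(sam)
    assert [r.reference_start for r in recs] == [100, 500]
    assert recs[1].is_reverse
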