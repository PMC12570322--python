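import numpy as np
import pytest

from metaguide.assembly import (AssemblyParams, AssemblyResult, ContigRecord,
                                assemble_with_reference, extract_contigs,
                                rank_references, should_continue)
from metaguide.io import Read
from metaguide.mapping import CoverageProfile, map_reads
from metaguide.refdb import ReferenceDatabase, ReferenceGenome
from metaguide.simdata import SimParams, mutate_strain, simulate_reads

from conftest import random_seq
from oracles import coverage_runs


def _cov(depth, span=None, clips=None):
    depth = np.asarray(depth)
    return CoverageProfile(
        "r", depth,
        np.asarray(span) if span is not None else depth.copy(),
        np.asarray(clips) if clips is not None else np.zeros(len(depth), int))


def test_extract_contigs_run_length_and_length_filter():
    depth = np.concatenate([np.zeros(100), np.ones(600), np.zeros(100),
                            np.ones(300)])
    ref = "A" * len(depth)
    # the 300 bp island is below the 500 bp contig floor
    assert extract_contigs(_cov(depth), ref) == [(100, 700)]
    full = np.ones(2000)
    assert extract_contigs(_cov(full), "A" * 2000) == [(0, 2000)]


def test_extract_contigs_matches_run_length_oracle():
    rng = np.random.default_rng(61)
    for trial in range(20):
        depth = rng.integers(0, 3, 3000) * (rng.random(3000) < 0.7)
        got = extract_contigs(_cov(depth), "A" * 3000)
        assert got == coverage_runs(depth, 500)


def test_extract_contigs_breaks_on_clip_evidence():
    """Positive depth with no spanning alignments and clustered clips splits
    the contig at the clip hotspot."""
    depth = np.ones(2000, int) * 5
    span = np.ones(2000, int) * 5
    span[990:1010] = 0
    clips = np.zeros(2000, int)
    clips[1000] = 4
    got = extract_contigs(_cov(depth, span, clips), "A" * 2000)
    assert got == [(0, 1000), (1000, 2000)]
    # without clip evidence there is no break
    got = extract_contigs(_cov(depth, span), "A" * 2000)
    assert got == [(0, 2000)]


def test_should_continue_criteria_boundaries():
    """Stop criteria use the quoted strict inequalities; singleton clusters
    always retain their assembly."""
    def result(cum, longest, ref_len=100_000):
        contigs = []
        remaining = cum
        while remaining > 0:
            size = min(longest, remaining)
            contigs.append(ContigRecord(f"c{len(contigs)}", "r", 0, size,
                                        "A" * size))
            remaining -= size
        return AssemblyResult("r", ref_len, contigs, {f"x{i}" for i in range(5)})

    # (iii): cumulative < 5% of the reference stops and discards
    d = should_continue(result(4900, 2500), False, 2, 1000)
    assert (d.retain, d.stop, d.reason) == (False, True, "iii")
    d = should_continue(result(5000, 2500), False, 2, 1000)
    assert (d.retain, d.stop) == (True, False)
    d = should_continue(result(5100, 2500), False, 2, 1000)
    assert (d.retain, d.stop) == (True, False)
    # (iv): longest below 2,000 stops; exactly 2,000 continues
    d = should_continue(result(6000, 1999), False, 2, 1000)
    assert (d.retain, d.stop, d.reason) == (False, True, "iv")
    d = should_continue(result(6000, 2000), False, 2, 1000)
    assert (d.retain, d.stop) == (True, False)
    # singleton retention: failing (iii)/(iv) keeps the assembly, loop ends
    # with (ii) because no references remain
    d = should_continue(result(800, 800), True, 0, 1000)
    assert (d.retain, d.stop, d.reason) == (True, True, "ii")
    # (i): all reads consumed
    d = should_continue(result(6000, 3000), False, 2, 5)
    assert (d.retain, d.stop, d.reason) == (True, True, "i")


def test_assemble_with_reference_ideal_and_sparse():
    rng = np.random.default_rng(62)
    seq = random_seq(rng, 50_000)
    reads, origins = simulate_reads([("G", seq, 1.0)], SimParams(depth=20, seed=62))
    res = assemble_with_reference(reads, ("G", seq))
    assert len(res.contigs) == 1
    assert res.breadth_of_ref >= 0.99
    assert res.cum_length == sum(len(c.sequence) for c in res.contigs)

    # consumed reads = exactly those whose origin lies within retained contigs
    (s, e), = [(c.ref_start, c.ref_end) for c in res.contigs]
    expected = {rid for rid, (_, pos, _) in origins.items()
                if pos < e and pos + 250 > s}
    assert res.consumed_read_ids == expected

    # reads covering only 2 kb of a 100 kb reference: cum/ref < 5%
    big = seq + random_seq(rng, 50_000)
    window = [r for r in reads if origins[r.id][1] < 1750]
    res2 = assemble_with_reference(window, ("G", big))
    assert 0 < res2.cum_length < 0.05 * len(big)
    d = should_continue(res2, False, 1, 10_000)
    assert (d.retain, d.stop, d.reason) == (False, True, "iii")

    # zero accepted alignments: empty result
    res3 = assemble_with_reference([Read("x", random_seq(rng, 250))], ("G", seq))
    assert res3.contigs == [] and res3.consumed_read_ids == set()


def test_rank_references_source_strain_first_then_accessory():
    """A cluster of two strains: the read-source strain ranks first; after its
    reads are consumed, accessory-bearing reads promote the sibling."""
    rng = np.random.default_rng(63)
    core = random_seq(rng, 20_000)
    accessory = random_seq(rng, 4000)
    strain_b = core[:10_000] + accessory + core[10_000:]
    # strain A diverges slightly so the two references are distinguishable
    strain_a, _, _ = mutate_strain(core, snp_rate=0.005, seed=63)
    ga = ReferenceGenome("A", [strain_a])
    gb = ReferenceGenome("B", [strain_b])
    db = ReferenceDatabase({"A": ga, "B": gb}, {})
    reads, _ = simulate_reads([("B", strain_b, 1.0)], SimParams(depth=10, seed=63))
    assert rank_references(["A", "B"], reads, db)[0] == "B"
    res = assemble_with_reference(reads, gb)
    remaining = [r for r in reads if r.id not in res.consumed_read_ids]
    # everything consumed by the perfect reference: sibling adds nothing
    assert len(remaining) < 0.01 * len(reads)

    # reads from A only: A first even though B contains the shared core
    reads_a, _ = simulate_reads([("A", strain_a, 1.0)], SimParams(depth=10, seed=64))
    order = rank_references(["A", "B"], reads_a, db)
    assert order[0] == "A"


def test_read_exclusivity_across_clusters(assembled):
    """No read id is consumed by two clusters or counted twice."""
    seen = set()
    for ca in assembled.clusters:
        for res in ca.results:
            assert not (seen & res.consumed_read_ids)
            seen |= res.consumed_read_ids
    assert seen.isdisjoint(set(assembled.leftover_read_ids))
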