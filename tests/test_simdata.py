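import numpy as np
import pytest

from metaguide.refdb import sketch
from metaguide.culling import estimate_ani
from metaguide.simdata import (SimParams, marker_templates, mutate_strain,
                               perturb_reference, simulate_community,
                               simulate_genome, simulate_reads)

from oracles import edit_distance, revcomp


def test_simulated_genome_is_deterministic_and_consistent():
    g1, m1, p1 = simulate_genome(100_000, seed=1)
    g2, m2, p2 = simulate_genome(100_000, seed=1)
    assert g1.sequences == g2.sequences
    assert p1 == p2
    assert [m.sequence for m in m1] == [m.sequence for m in m2]
    assert simulate_genome(100_000, seed=2)[0].sequences != g1.sequences

    # planted intervals are non-overlapping and reproduce the marker FASTA
    seq = g1.sequences[0]
    ivs = sorted(p1.values())
    assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(ivs, ivs[1:]))
    for m in m1:
        s, e = p1[m.family]
        assert seq[s:e] == m.sequence
    assert len(p1) == 40

    with pytest.raises(ValueError, match="too small"):
        simulate_genome(10_000, n_marker_families=40)


def test_mutate_strain_truth_and_ani():
    rng = np.random.default_rng(81)
    base = simulate_genome(50_000, n_marker_families=0, seed=81)[0].sequences[0]
    same, variants, _ = mutate_strain(base, snp_rate=0.0, seed=1)
    assert same == base and variants == []

    # 2% substitutions: sketch ANI to the parent lands near 98 (10 seeds)
    anis = [estimate_ani(sketch(base),
                         sketch(mutate_strain(base, 0.02, seed=s)[0]))
            for s in range(10)]
    assert abs(np.mean(anis) - 98.0) <= 0.5

    # accessory 5 kb insertion recorded with exact coordinates
    strain, variants, shifted = mutate_strain(
        base, seed=2, segment_gains=[(20_000, 5000)],
        intervals={"x": (30_000, 31_000)})
    gain = [v for v in variants if v["type"] == "segment_gain"][0]
    assert strain[20_000:25_000] == gain["alt"]
    assert strain[:20_000] == base[:20_000]
    assert shifted["x"] == (35_000, 36_000)
    assert edit_distance(base, strain) == 5000

    with pytest.raises(ValueError, match="rates"):
        mutate_strain(base, snp_rate=0.5)


def test_simulated_read_counts_and_exactness():
    rng = np.random.default_rng(82)
    seq = simulate_genome(50_000, n_marker_families=0, seed=82)[0].sequences[0]
    reads, origins = simulate_reads([("G", seq, 1.0)],
                                    SimParams(depth=20, seed=82))
    # closed form: round(20 * 50000 / (2 * 250)) pairs
    assert len(reads) == 2 * 2000
    assert len(origins) == len(reads)
    # error-free reads are exact substrings (or reverse complements)
    for r in reads[:300]:
        acc, pos, strand = origins[r.id]
        expect = seq[pos:pos + 250]
        assert r.seq == (expect if strand == "+" else revcomp(expect))
    # empirical depth within 5% of nominal
    depth = np.zeros(len(seq))
    for _, pos, _ in origins.values():
        depth[pos:pos + 250] += 1
    assert abs(depth.mean() - 20) / 20 <= 0.05
    # determinism
    reads2, _ = simulate_reads([("G", seq, 1.0)], SimParams(depth=20, seed=82))
    assert reads2 == reads


def test_abundance_weighting_is_proportional():
    rng = np.random.default_rng(83)
    seqs = [simulate_genome(30_000, 0, seed=s)[0].sequences[0] for s in (1, 2)]
    reads, origins = simulate_reads(
        [("A", seqs[0], 1.0), ("B", seqs[1], 0.25)], SimParams(depth=8, seed=83))
    n_a = sum(1 for acc, _, _ in origins.values() if acc == "A")
    n_b = len(origins) - n_a
    assert n_a == 2 * round(8 * 30_000 / 500)
    assert n_b == 2 * round(2 * 30_000 / 500)


def test_perturbations_roundtrip():
    seq = simulate_genome(50_000, n_marker_families=0, seed=84)[0].sequences[0]
    guide, truth = perturb_reference(seq, "insertion", 250, seed=84)
    assert len(guide) == len(seq) + 250
    p = truth.position
    assert guide[p:p + 250] == truth.segment
    assert guide[:p] + guide[p + 250:] == seq  # inverse edit restores

    guide, truth = perturb_reference(seq, "deletion", 500, seed=84)
    assert len(guide) == len(seq) - 500
    p = truth.position
    assert guide[:p] + truth.segment + guide[p:] == seq
    assert truth.segment == seq[p:p + 500]

    with pytest.raises(ValueError):
        perturb_reference(seq, "inversion", 100)
    with pytest.raises(ValueError):
        perturb_reference(seq[:3000], "insertion", 100)


def test_community_marker_sharing_exercises_clustering():
    """Family templates are shared: within-family copies diverge by a few
    percent across genomes, far more across families."""
    truth, genomes, markers = simulate_community(
        2, lengths=(50_000, 50_000), weights=[1, 1], seed=85)
    by_family = {}
    for m in markers:
        by_family.setdefault(m.family, []).append(m.sequence)
    tmpl = marker_templates(85)
    for fam, (a, b) in list(by_family.items())[:5]:
        d_ab = edit_distance(a, b) / len(a)
        assert 0.05 < d_ab < 0.30          # same family, different genome
        d_t = edit_distance(a, tmpl[fam - 1]) / len(a)
        assert d_t < 0.15                   # close to the family template
    other = edit_distance(by_family[1][0], by_family[2][0]) / 800
    assert other > 0.4                      # different families: unrelated
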