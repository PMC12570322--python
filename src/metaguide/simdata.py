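"""Synthetic communities with known truth, for exercising the pipeline.

Everything here is a pure function of (parameters, seed).  The generator
emulates: multi-species communities with log-varying abundances; planted
universal single-copy marker genes (40 families, ~800 bp, shared across
genomes at a few percent divergence so 99% marker clustering is exercised);
strain-level variation (SNPs, small indels, accessory segments); 250 bp
paired reads with i.i.d. substitution errors; and guide-reference
perturbation experiments (random-alphabet insertions, segment deletions).

It does not emulate realistic error profiles (quality ramps, indel errors),
GC bias, or repeat structure: backgrounds are i.i.d. random sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import revcomp
from .io import Read
from .refdb import MarkerGene, ReferenceGenome

_ALPH = np.array(list("ACGT"))

#: default marker template length (bases)
MARKER_LENGTH = 800
#: divergence of each genome's marker copy from the family template; species
#: must differ enough in their marker complement that reads never cross-map
#: (universal markers diverge well beyond read-mapping identity across
#: species), while strain variants of one genome stay above the 99% marker
#: clustering threshold
TEMPLATE_DIVERGENCE = 0.08


@dataclass
class SimParams:
    """Read-simulation settings (defaults model ~250 bp paired short reads)."""

    read_length: int = 250
    depth: float = 20.0
    error_rate: float = 0.0
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    seed: int = 0


@dataclass
class PerturbationTruth:
    mode: str           # "insertion" | "deletion"
    position: int       # guide coordinate of the event
    length: int
    segment: str        # inserted (guide coords) or removed (original) bases

    @property
    def interval(self) -> tuple[int, int]:
        """Perturbed interval in guide coordinates (point for deletions)."""
        if self.mode == "insertion":
            return (self.position, self.position + self.length)
        return (self.position, self.position)


@dataclass
class CommunityTruth:
    """Ground truth of a simulated community."""

    genomes: list[tuple[str, str, float]]  # (accession, sequence, weight)
    variants: dict[str, list[dict]] = field(default_factory=dict)
    marker_placements: dict[str, dict[int, tuple[int, int]]] = field(default_factory=dict)
    read_origins: dict[str, tuple[str, int, str]] = field(default_factory=dict)


def _random_seq(rng, length: int) -> str:
    return "".join(_ALPH[rng.integers(0, 4, length)])


def marker_templates(seed: int, n_families: int = 40,
                     length: int = MARKER_LENGTH) -> list[str]:
    """Family-specific random marker templates (one per family)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    return [_random_seq(rng, length) for _ in range(n_families)]


def _diverge(rng, seq: str, rate: float) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    lut = {b: [o for o in b"ACGT" if o != b] for b in b"ACGT"}
    for i in hits:
        codes[i] = lut[codes[i]][rng.integers(0, 3)]
    return codes.tobytes().decode()


def simulate_genome(length: int, n_marker_families: int = 40, seed: int = 0,
                    accession: str = "G1", templates: list[str] | None = None,
                    template_divergence: float = TEMPLATE_DIVERGENCE,
                    ) -> tuple[ReferenceGenome, list[MarkerGene], dict[int, tuple[int, int]]]:
    """Random genome with marker genes planted at non-overlapping positions.

    Returns (genome, markers, placements) where placements maps family ->
    half-open interval.  Marker sequences are the family templates diverged by
    ``template_divergence`` so different genomes carry recognisably distinct
    copies of the same family.
    """
    if templates is None:
        templates = marker_templates(seed, n_marker_families)
    tlen = max(len(t) for t in templates) if templates else 0
    block = length // max(n_marker_families, 1) if n_marker_families else length
    if n_marker_families and block < tlen + 20:
        raise ValueError(
            f"genome length {length} too small to plant {n_marker_families} "
            f"markers of {tlen} bp")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
    seq = list(_random_seq(rng, length))
    markers: list[MarkerGene] = []
    placements: dict[int, tuple[int, int]] = {}
    for fam in range(1, n_marker_families + 1):
        tmpl = templates[fam - 1]
        copy = _diverge(rng, tmpl, template_divergence)
        lo = (fam - 1) * block
        start = lo + int(rng.integers(0, block - len(copy) + 1))
        seq[start:start + len(copy)] = copy
        placements[fam] = (start, start + len(copy))
        markers.append(MarkerGene(f"{accession}_m{fam:02d}", fam, accession, copy))
    genome = ReferenceGenome(accession, ["".join(seq)],
                             [m.marker_id for m in markers])
    return genome, markers, placements


def mutate_strain(sequence: str, snp_rate: float = 0.0, indel_rate: float = 0.0,
                  seed: int = 0, max_indel: int = 10,
                  segment_gains: list[tuple[int, int]] | None = None,
                  segment_losses: list[tuple[int, int]] | None = None,
                  intervals: dict | None = None,
                  ) -> tuple[str, list[dict], dict]:
    """Derive a strain: substitutions, small indels, accessory segments.

    ``segment_gains`` are (position, length) random-alphabet insertions;
    ``segment_losses`` are (position, length) deletions.  Returns
    (strain_sequence, variants, shifted_intervals); ``intervals`` (e.g.
    marker placements) are lifted through the coordinate changes.  Expected
    ANI to the parent is about 100 * (1 - snp_rate).
    """
    if not 0 <= snp_rate <= 0.1 or not 0 <= indel_rate <= 0.1:
        raise ValueError("mutation rates must lie in [0, 0.1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7003]))
    L = len(sequence)
    variants: list[dict] = []
    for pos in np.nonzero(rng.random(L) < snp_rate)[0]:
        ref = sequence[pos]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        variants.append({"type": "snp", "pos": int(pos), "ref": ref, "alt": alt})
    n_indels = int(np.round(indel_rate * L))
    if n_indels:
        for pos in sorted(rng.choice(L - max_indel, n_indels, replace=False)):
            ilen = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                variants.append({"type": "ins", "pos": int(pos), "ref": "",
                                 "alt": _random_seq(rng, ilen)})
            else:
                variants.append({"type": "del", "pos": int(pos),
                                 "ref": sequence[pos:pos + ilen], "alt": ""})
    for pos, ln in (segment_gains or []):
        variants.append({"type": "segment_gain", "pos": int(pos), "ref": "",
                         "alt": _random_seq(rng, ln)})
    for pos, ln in (segment_losses or []):
        variants.append({"type": "segment_loss", "pos": int(pos),
                         "ref": sequence[pos:pos + ln], "alt": ""})
    variants.sort(key=lambda v: (v["pos"], v["type"]))
    # apply left-to-right; all positions refer to the parent sequence
    out = []
    shift_points: list[tuple[int, int]] = []  # (parent pos, cumulative shift)
    cursor = 0
    shift = 0
    for v in variants:
        pos = v["pos"]
        if pos < cursor:  # overlapping events: keep the first
            continue
        out.append(sequence[cursor:pos])
        if v["type"] == "snp":
            out.append(v["alt"])
            cursor = pos + 1
        else:
            out.append(v["alt"])
            cursor = pos + len(v["ref"])
            shift += len(v["alt"]) - len(v["ref"])
            shift_points.append((cursor, shift))
    out.append(sequence[cursor:])
    strain = "".join(out)

    def lift(p: int) -> int:
        s = 0
        for pp, sh in shift_points:
            if pp <= p:
                s = sh
            else:
                break
        return p + s

    shifted = {}
    for name, (s, e) in (intervals or {}).items():
        shifted[name] = (lift(s), lift(e))
    return strain, variants, shifted


def simulate_reads(community, params: SimParams | None = None
                   ) -> tuple[list[Read], dict[str, tuple[str, int, str]]]:
    """Abundance-weighted paired reads with i.i.d. substitution errors.

    ``community`` is a :class:`CommunityTruth` or a list of
    ``(accession, sequence, weight)``.  A genome at weight 1.0 is sampled at
    ``params.depth`` fold-coverage; pair counts scale with weight * length.
    Returns (reads, origins) with origins[read_id] = (genome, position,
    strand); mates are independent reads (ids suffixed :1 / :2).
    """
    params = params or SimParams()
    genomes = community.genomes if isinstance(community, CommunityTruth) else list(community)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7004]))
    rl = params.read_length
    reads: list[Read] = []
    origins: dict[str, tuple[str, int, str]] = {}
    for acc, seq, weight in genomes:
        L = len(seq)
        n_pairs = int(np.round(params.depth * weight * L / (2 * rl)))
        frags = np.clip(np.round(rng.normal(params.insert_mean, params.insert_sd,
                                            n_pairs)).astype(int), rl, L)
        starts = (rng.random(n_pairs) * (L - frags + 1)).astype(int)
        for i in range(n_pairs):
            s, f = int(starts[i]), int(frags[i])
            fwd = seq[s:s + rl]
            rev = revcomp(seq[s + f - rl:s + f])
            for mate, (rseq, pos, strand) in enumerate(
                    ((fwd, s, "+"), (rev, s + f - rl, "-")), start=1):
                if params.error_rate > 0:
                    rseq = _diverge(rng, rseq, params.error_rate)
                rid = f"{acc}:{i}:{mate}"
                reads.append(Read(rid, rseq))
                origins[rid] = (acc, pos, strand)
    if isinstance(community, CommunityTruth):
        community.read_origins = origins
    return reads, origins


def perturb_reference(sequence: str, mode: str, length: int, seed: int = 0,
                      min_margin: int = 2000) -> tuple[str, PerturbationTruth]:
    """Plant a single insertion or deletion into a guide reference copy.

    Insertions add ``length`` bases of random alphabet at a random interior
    position; deletions remove ``length`` bases.  The locus stays at least
    ``min_margin`` bases from either sequence end.
    """
    if length <= 0:
        raise ValueError("perturbation length must be positive")
    if len(sequence) < 2 * min_margin + length + 1:
        raise ValueError("sequence too short for the requested perturbation")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7005, length]))
    if mode == "insertion":
        pos = int(rng.integers(min_margin, len(sequence) - min_margin))
        seg = _random_seq(rng, length)
        guide = sequence[:pos] + seg + sequence[pos:]
        return guide, PerturbationTruth("insertion", pos, length, seg)
    if mode == "deletion":
        pos = int(rng.integers(min_margin, len(sequence) - min_margin - length))
        seg = sequence[pos:pos + length]
        guide = sequence[:pos] + sequence[pos + length:]
        return guide, PerturbationTruth("deletion", pos, length, seg)
    raise ValueError(f"unknown perturbation mode {mode!r}")


def simulate_community(n_genomes: int = 3, lengths=(100_000, 80_000, 60_000),
                       weights=None, seed: int = 0, n_marker_families: int = 40,
                       strain_snp_rate: float = 0.0,
                       ) -> tuple[CommunityTruth, list[ReferenceGenome], list[MarkerGene]]:
    """A multi-species community plus matching reference-database inputs.

    Default abundances vary on a log scale (one decade across the community).
    When ``strain_snp_rate`` > 0 the database genomes are strain variants of
    the community genomes rather than exact copies.
    """
    if weights is None:
        weights = np.logspace(0, -1, n_genomes)
    templates = marker_templates(seed, n_marker_families)
    truth = CommunityTruth(genomes=[])
    db_genomes: list[ReferenceGenome] = []
    db_markers: list[MarkerGene] = []
    for g in range(n_genomes):
        acc = f"SIM{g + 1:03d}"
        genome, markers, placements = simulate_genome(
            lengths[g % len(lengths)], n_marker_families, seed=seed * 101 + g,
            accession=acc, templates=templates)
        truth.genomes.append((acc, genome.sequences[0], float(weights[g])))
        truth.marker_placements[acc] = placements
        if strain_snp_rate > 0:
            strain, variants, shifted = mutate_strain(
                genome.sequences[0], snp_rate=strain_snp_rate,
                seed=seed * 211 + g, intervals=placements)
            truth.variants[acc] = variants
            db_genomes.append(ReferenceGenome(acc, [strain],
                                              [m.marker_id for m in markers]))
            db_markers.extend(
                MarkerGene(m.marker_id, m.family, acc,
                           strain[shifted[m.family][0]:shifted[m.family][1]])
                for m in markers)
        else:
            db_genomes.append(genome)
            db_markers.extend(markers)
    return truth, db_genomes, db_markers


def insertion_bias_scan(seed: int = 0, genome_length: int = 200_000,
                        depth: float = 20.0, read_length: int = 250,
                        lengths=tuple(range(125, 1251, 125)),
                        mode: str = "insertion") -> dict[int, bool]:
    """Guide-perturbation experiment: does the guided map -> coverage-break ->
    contig-extraction stage place a contig boundary at the perturbed locus?

    Simulates error-free paired reads from an unperturbed genome, perturbs a
    guide copy for each length on the grid, and runs the contig-extraction
    stage with default parameters.  Returns {length: break_at_locus}.
    """
    from .assembly import AssemblyParams, extract_contigs
    from .mapping import MapperParams, compute_coverage, map_reads

    genome, _, _ = simulate_genome(genome_length, n_marker_families=40,
                                   seed=seed, accession="BIAS")
    seq = genome.sequences[0]
    reads, _ = simulate_reads([("BIAS", seq, 1.0)],
                              SimParams(read_length=read_length, depth=depth,
                                        error_rate=0.0, seed=seed))
    mparams = MapperParams()
    out: dict[int, bool] = {}
    for L in lengths:
        guide, truth = perturb_reference(seq, mode, L, seed=seed)
        alignments = map_reads(reads, ("guide", guide), mparams)
        cov = compute_coverage(alignments, len(guide), mparams.anchor_min,
                               ref_id="guide")
        contigs = extract_contigs(cov, guide, AssemblyParams())
        lo, hi = truth.interval
        if mode == "deletion":
            # the cut lands within a few bases of the point junction
            lo, hi = lo - 10, hi + 10
        boundaries = [b for s, e in contigs for b in (s, e)
                      if b not in (0, len(guide))]
        out[L] = any(lo <= b <= hi for b in boundaries)
    return out


def largest_unbroken_insertion(seed: int = 0, **kwargs) -> int:
    """Largest grid insertion length that does not break contiguity."""
    scan = insertion_bias_scan(seed=seed, **kwargs)
    unbroken = [L for L, broke in scan.items() if not broke]
    return max(unbroken) if unbroken else 0
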