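"""Guided assembly: greedy within-cluster reference ordering, coverage-break
contig extraction, and the sample-level assembly loop.

Within an ANI cluster, references are processed greedily (set-cover style):
the genome whose sketch has the highest containment in the unassigned-read
k-mer hashes is assembled first, its reads are consumed, and the ranking is
recomputed.  Assembly of a cluster stops when (i) all reads are assembled,
(ii) all references are assembled, (iii) the cumulative contig length fails
to reach 5% of the reference length, or (iv) the longest contig is shorter
than 2,000 bp; a genome stopping on (iii)/(iv) contributes nothing unless the
cluster is a singleton, whose assembly is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import canonical_kmer_codes, encode, hash64, kmer_code_set
from .culling import AniParams, GenomeCluster, cluster_genomes, cluster_kmer_sets, next_cluster
from .mapping import MapperParams, compute_coverage, map_reads, pileup
from .polish import PolishEdit, PolishParams, polish_contig
from .refdb import KmerSet, ReferenceDatabase, ReferenceGenome
from .selection import SelectionParams, screen_markers, select_references

@dataclass(frozen=True)
class AssemblyParams:
    min_contig_final: int = 500      # drop shorter reference spans
    min_longest_contig: int = 2000   # stopping criterion (iv)
    min_cum_fraction: float = 0.05   # stopping criterion (iii)
    clip_min: int = 2                # clipped alignments needed to call a break

    def __post_init__(self):
        if min(self.min_contig_final, self.min_longest_contig) <= 0 \
                or self.min_cum_fraction <= 0:
            raise ValueError("assembly parameters must be positive")


@dataclass
class ContigRecord:
    contig_id: str
    ref_accession: str
    ref_start: int   # pre-polish placement, 0-based half-open
    ref_end: int
    sequence: str    # polished
    edits: list[PolishEdit] = field(default_factory=list)


@dataclass
class AssemblyResult:
    ref_accession: str
    ref_length: int
    contigs: list[ContigRecord] = field(default_factory=list)
    consumed_read_ids: set[str] = field(default_factory=set)

    @property
    def cum_length(self) -> int:
        return sum(len(c.sequence) for c in self.contigs)

    @property
    def longest(self) -> int:
        return max((len(c.sequence) for c in self.contigs), default=0)

    @property
    def breadth_of_ref(self) -> float:
        span = sum(c.ref_end - c.ref_start for c in self.contigs)
        return span / self.ref_length if self.ref_length else 0.0


@dataclass
class Decision:
    retain: bool
    stop: bool
    reason: str | None  # i | ii | iii | iv


@dataclass
class ClusterAssembly:
    cluster: GenomeCluster
    results: list[AssemblyResult] = field(default_factory=list)
    stop_log: list[str] = field(default_factory=list)


@dataclass
class SampleAssembly:
    clusters: list[ClusterAssembly] = field(default_factory=list)
    selected: list[tuple[str, int]] = field(default_factory=list)
    leftover_read_ids: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def all_contigs(self) -> list[tuple[int, AssemblyResult, ContigRecord]]:
        return [(ca.cluster.cluster_id, res, c)
                for ca in self.clusters for res in ca.results
                for c in res.contigs]


def read_hash_set(reads, k: int = 21, hash_seed: int = 42) -> np.ndarray:
    """Sorted unique canonical k-mer hashes over a read set."""
    parts = [canonical_kmer_codes(encode(r.seq), k) for r in reads]
    parts = [p for p in parts if len(p)]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(hash64(np.concatenate(parts), hash_seed))


def rank_references(cluster, unassigned_reads, database: ReferenceDatabase,
                    read_hashes: np.ndarray | None = None) -> list[str]:
    """Cluster members ordered by sketch containment in the unassigned reads.

    Containment of a genome = fraction of its sketch hashes found among the
    canonical 21-mer hashes of the unassigned reads (genome-in-reads fit, the
    greedy set-cover surrogate).  Ties break on accession.
    """
    members = cluster.members if isinstance(cluster, GenomeCluster) else list(cluster)
    if read_hashes is None:
        read_hashes = read_hash_set(unassigned_reads, database.sketch_k,
                                    database.hash_seed)
    scored = [(-database.genome_sketch(acc).containment_in(read_hashes), acc)
              for acc in members]
    scored.sort()
    return [acc for _, acc in scored]


def extract_contigs(coverage, reference: str,
                    params: AssemblyParams | None = None) -> list[tuple[int, int]]:
    """Pre-polish contig intervals from a coverage profile.

    Maximal positive-depth runs form candidate contigs; additionally, a
    position with positive depth but zero spanning depth and clip evidence
    from >= ``clip_min`` alignments is a break point (the signature of a
    structural difference the reads cannot bridge).  Intervals whose
    reference span is shorter than ``min_contig_final`` are discarded.
    """
    params = params or AssemblyParams()
    depth = coverage.depth
    covered = depth > 0
    # structural break evidence: clips within +-2 bases
    clips = coverage.clips
    if clips is not None and len(clips):
        kernel = np.ones(5, dtype=np.int64)
        clipwin = np.convolve(clips, kernel, mode="same")
    else:
        clipwin = np.zeros(len(depth), dtype=np.int64)
    breakable = covered & (coverage.span_depth == 0) & (clipwin >= params.clip_min)
    intervals: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        cuts = []
        cand = np.flatnonzero(breakable[s:e]) + s
        if len(cand):
            runs = np.split(cand, np.flatnonzero(np.diff(cand) > 1) + 1)
            for run in runs:
                # cut where the clip signal peaks (exact clip point first)
                score = clips[run].astype(np.int64) * (clipwin.max() + 1) \
                    + clipwin[run]
                cut = int(run[np.argmax(score)])
                if s < cut < e:
                    cuts.append(cut)
        for a, b in zip([int(s)] + cuts, cuts + [int(e)]):
            if b - a >= params.min_contig_final:
                intervals.append((a, b))
    return intervals


def assemble_with_reference(reads, reference, mapper_params: MapperParams | None = None,
                            polish_params: PolishParams | None = None,
                            params: AssemblyParams | None = None,
                            cluster_id: int = 0) -> AssemblyResult:
    """One guided pass: map -> coverage -> break -> extract -> polish.

    ``reference`` is a :class:`ReferenceGenome` or ``(accession, seq)``.
    Consumed reads are those whose primary alignment overlaps a retained
    contig interval; reads over discarded short islands stay available to
    sibling references.
    """
    mapper_params = mapper_params or MapperParams()
    polish_params = polish_params or PolishParams()
    params = params or AssemblyParams()
    if isinstance(reference, tuple):
        reference = ReferenceGenome(reference[0], [reference[1]])
    acc = reference.accession
    result = AssemblyResult(ref_accession=acc, ref_length=reference.total_length)
    ordinal = 0
    for si, seq in enumerate(reference.sequences):
        ref_id = acc if len(reference.sequences) == 1 else f"{acc}/{si}"
        alignments = map_reads(reads, (ref_id, seq), mapper_params)
        if not alignments:
            continue
        cov = compute_coverage(alignments, len(seq), mapper_params.anchor_min,
                               ref_id=ref_id)
        intervals = extract_contigs(cov, seq, params)
        if not intervals:
            continue
        pile = pileup(alignments, (ref_id, seq))
        starts = np.array([iv[0] for iv in intervals])
        ends = np.array([iv[1] for iv in intervals])
        for a in alignments:
            if np.any((a.ref_start < ends) & (a.ref_end > starts)):
                result.consumed_read_ids.add(a.read_id)
        for s, e in intervals:
            polished, edits = polish_contig((s, e), seq, pile, polish_params)
            ordinal += 1
            result.contigs.append(ContigRecord(
                contig_id=f"cluster{cluster_id}|{ref_id}|{ordinal}",
                ref_accession=ref_id, ref_start=int(s), ref_end=int(e),
                sequence=polished, edits=edits))
    return result


def should_continue(result: AssemblyResult, is_singleton_cluster: bool,
                    remaining_refs: int, remaining_reads: int,
                    params: AssemblyParams | None = None) -> Decision:
    """Stop/continue decision after one guided pass (criteria i-iv).

    Criteria (iii) cumulative length < 5% of reference length and (iv)
    longest contig < 2,000 bp use strict inequalities; in a multi-genome
    cluster a failing genome's assembly is discarded and the cluster stops,
    while a singleton cluster's assembly is always retained.
    """
    params = params or AssemblyParams()
    fail_iii = result.cum_length < params.min_cum_fraction * result.ref_length
    fail_iv = result.longest < params.min_longest_contig
    if (fail_iii or fail_iv) and not is_singleton_cluster:
        return Decision(retain=False, stop=True,
                        reason="iii" if fail_iii else "iv")
    if remaining_reads - len(result.consumed_read_ids) <= 0:
        return Decision(retain=True, stop=True, reason="i")
    if remaining_refs <= 0:
        return Decision(retain=True, stop=True, reason="ii")
    return Decision(retain=True, stop=False, reason=None)


def assemble_sample(reads, database: ReferenceDatabase,
                    selection_params: SelectionParams | None = None,
                    ani_params: AniParams | None = None,
                    mapper_params: MapperParams | None = None,
                    polish_params: PolishParams | None = None,
                    params: AssemblyParams | None = None) -> SampleAssembly:
    """Full pipeline: screen -> select -> cull -> per-cluster guided assembly.

    Returns a :class:`SampleAssembly`; when no reference clears selection the
    run succeeds with an explicit "no references selected" log entry and all
    reads left over.
    """
    selection_params = selection_params or SelectionParams()
    ani_params = ani_params or AniParams()
    mapper_params = mapper_params or MapperParams()
    params = params or AssemblyParams()
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("read ids must be unique")
    out = SampleAssembly()
    table = screen_markers(reads, database, selection_params, mapper_params)
    out.selected = select_references(table, database, selection_params)
    if not out.selected:
        out.log.append("no references selected")
        out.leftover_read_ids = list(ids)
        return out
    accs = [acc for acc, _ in out.selected]
    out.log.append(f"selected {len(accs)} reference(s): {', '.join(accs)}")
    sketches = {acc: database.genome_sketch(acc) for acc in accs}
    lengths = {acc: database.genomes[acc].total_length for acc in accs}
    clusters = cluster_genomes(accs, sketches, ani_params, lengths)
    ckmers = cluster_kmer_sets(clusters, database)
    out.log.append(f"{len(clusters)} ANI cluster(s)")
    unassigned: dict[str, object] = {r.id: r for r in reads}
    processed: set[int] = set()
    while unassigned:
        read_kmers = KmerSet(k=database.kmer_k,
                             codes=kmer_code_set([r.seq for r in unassigned.values()],
                                                 database.kmer_k))
        cluster = next_cluster(clusters, processed, read_kmers, ckmers)
        if cluster is None:
            break
        processed.add(cluster.cluster_id)
        ca = ClusterAssembly(cluster=cluster)
        out.clusters.append(ca)
        remaining = list(cluster.members)
        singleton = len(cluster.members) == 1
        while remaining and unassigned:
            pool = list(unassigned.values())
            order = rank_references(remaining, pool, database)
            acc = order[0]
            remaining.remove(acc)
            result = assemble_with_reference(
                pool, database.genomes[acc], mapper_params,
                polish_params=polish_params, params=params,
                cluster_id=cluster.cluster_id)
            decision = should_continue(result, singleton, len(remaining),
                                       len(unassigned), params)
            if decision.retain:
                ca.results.append(result)
                for rid in result.consumed_read_ids:
                    unassigned.pop(rid, None)
            ca.stop_log.append(
                f"{acc}: contigs={len(result.contigs)} cum={result.cum_length} "
                f"longest={result.longest} retain={decision.retain} "
                f"stop={decision.stop} reason={decision.reason}")
            if decision.stop:
                break
    out.leftover_read_ids = [rid for rid in ids if rid in unassigned]
    out.log.extend(line for ca in out.clusters for line in ca.stop_log)
    return out
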