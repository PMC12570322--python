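"""Redundancy culling: ANI clustering of selected references and iterative
cluster prioritisation against the unassigned-read k-mer set.

ANI is estimated from bottom-s MinHash sketches with the Mash distance
formula; genomes at >= 95% estimated ANI (the conventional prokaryotic
species boundary) fall into one single-linkage cluster.  Clusters are then
processed in order of the size of the intersection between the cluster's
28-mer set and the 28-mers of the still-unassigned reads, recomputed before
each pick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .refdb import KmerSet, Sketch


@dataclass(frozen=True)
class AniParams:
    ani_threshold: float = 95.0  # percent
    linkage: str = "single"

    def __post_init__(self):
        if not 0 < self.ani_threshold <= 100:
            raise ValueError("ani_threshold must be in (0, 100]")
        if self.linkage != "single":
            raise ValueError("only single linkage is supported")


@dataclass
class GenomeCluster:
    cluster_id: int
    members: list[str]
    representative_length: int
    score: int = 0  # last computed k-mer intersection with unassigned reads


def estimate_ani(a: Sketch, b: Sketch) -> float:
    """Mash-style ANI percent from two sketches (0 when sketches are disjoint).

    j is the bottom-s Jaccard estimate; distance D = -ln(2j/(1+j))/k and
    ANI = 100 * (1 - D), floored at 0.
    """
    j = a.jaccard(b)
    if j <= 0:
        return 0.0
    d = -math.log(2 * j / (1 + j)) / a.k
    return max(100.0 * (1.0 - d), 0.0)


def cluster_genomes(candidates: list[str], sketches: dict[str, Sketch],
                    params: AniParams | None = None,
                    lengths: dict[str, int] | None = None,
                    ani_func=estimate_ani) -> list[GenomeCluster]:
    """Single-linkage components over the >= threshold ANI graph.

    Clusters are numbered by their smallest member accession; members are
    sorted.  ``ani_func`` is injectable for testing.
    """
    params = params or AniParams()
    parent = {acc: acc for acc in candidates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ordered = sorted(candidates)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if ani_func(sketches[a], sketches[b]) >= params.ani_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for acc in ordered:
        groups.setdefault(find(acc), []).append(acc)
    clusters = []
    for cid, root in enumerate(sorted(groups)):
        members = sorted(groups[root])
        if lengths:
            rep_len = max(lengths[m] for m in members)
        else:
            rep_len = max(s.source_length for m in members
                          for s in [sketches[m]])
        clusters.append(GenomeCluster(cid, members, rep_len))
    return clusters


def next_cluster(clusters: list[GenomeCluster], processed: set[int],
                 unassigned_read_kmers: KmerSet,
                 cluster_kmers: dict[int, KmerSet],
                 min_intersection: int = 1) -> GenomeCluster | None:
    """Unprocessed cluster with the largest read k-mer intersection.

    Scores are recomputed against the current unassigned-read k-mer set;
    ties break on cluster_id.  Returns None when every cluster is processed
    or the best intersection falls below ``min_intersection`` distinct
    k-mers (zero-overlap clusters cannot recruit reads).
    """
    best = None
    for c in clusters:
        if c.cluster_id in processed:
            continue
        c.score = cluster_kmers[c.cluster_id].intersection_size(unassigned_read_kmers)
        if best is None or c.score > best.score:
            best = c
    if best is None or best.score < min_intersection:
        return None
    return best


def cluster_kmer_sets(clusters: list[GenomeCluster], database) -> dict[int, KmerSet]:
    """Union 28-mer set per cluster (static across the iteration)."""
    import numpy as np

    out = {}
    for c in clusters:
        codes = [database.genome_kmer_set(m).codes for m in c.members]
        out[c.cluster_id] = KmerSet(k=database.kmer_k,
                                    codes=np.unique(np.concatenate(codes)))
    return out
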