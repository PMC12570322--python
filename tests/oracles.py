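"""Brute-force reference implementations used as independent test oracles.

Everything here favours obviousness over speed and stays independent of the
package internals it checks (only plain Python / numpy / edlib).
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, revcomp(km)))
    return out


def exact_jaccard(a: str, b: str, k: int) -> float:
    sa, sb = canonical_kmers(a, k), canonical_kmers(b, k)
    return len(sa & sb) / len(sa | sb) if sa | sb else 0.0


def interval_depth(intervals, length: int) -> np.ndarray:
    """Per-base counting of half-open intervals, one position at a time."""
    depth = np.zeros(length, dtype=int)
    for s, e in intervals:
        for i in range(s, e):
            depth[i] += 1
    return depth


def union_breadth(intervals, length: int) -> float:
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return len(covered) / length


def coverage_runs(depth, min_len: int) -> list[tuple[int, int]]:
    """Maximal positive runs of a depth vector, filtered by length."""
    runs = []
    start = None
    for i, d in enumerate(list(depth) + [0]):
        if d > 0 and start is None:
            start = i
        elif d <= 0 and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def greedy_identity_clusters(seqs: dict[str, str], threshold: float) -> int:
    """Greedy longest-first clustering by edlib global identity; returns the
    number of clusters."""
    import edlib

    def identity(a, b):
        res = edlib.align(a, b, mode="NW", task="path")
        cols = sum(int(n) for n in
                   __import__("re").findall(r"(\d+)", res["cigar"]))
        return (cols - res["editDistance"]) / cols

    reps = []
    for name in sorted(seqs, key=lambda n: (-len(seqs[n]), n)):
        if not any(identity(seqs[name], seqs[r]) >= threshold for r in reps):
            reps.append(name)
    return len(reps)


def connected_components(nodes, edges) -> list[list[str]]:
    """BFS connected components; components sorted by smallest member."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = []
    for n in sorted(nodes):
        if n in seen:
            continue
        comp, queue = [], [n]
        while queue:
            x = queue.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            queue.extend(adj[x] - seen)
        comps.append(sorted(comp))
    return sorted(comps, key=lambda c: c[0])


def ngx_all_prefixes(lengths, genome_size: int, x: float):
    """NGx by scanning every prefix of the sorted length list."""
    lens = sorted(lengths, reverse=True)
    for i in range(len(lens)):
        if sum(lens[:i + 1]) > x / 100 * genome_size:
            return lens[i]
    return None


def edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
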