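"""Internal short-read mapper plus coverage and pileup construction.

The mapper is seed-chain-extend: exact 15-mer seeds against a sorted k-mer
index of the reference, diagonal clustering of seed hits, then affine-gap
local alignment (``_align``) of the read against a reference window around
the best diagonal band.  Reads that match a single diagonal with only a few
substitutions skip the DP entirely.

Design contract (what downstream stages rely on):

* at most one primary alignment per read, deterministic tie-breaking;
* a single insertion/deletion of up to ``max_gap`` bases (default half the
  read length) may be embedded in an alignment; anything longer causes the
  read to be clipped to its best-scoring side instead;
* identity is gap-compressed (a contiguous gap counts as one column), so an
  embedded 125 bp gap in a 250 bp read does not disqualify the alignment;
* acceptance requires gap-compressed identity >= ``min_identity`` over at
  least ``anchor_min`` matched+mismatched columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._align import local_align
from ._kmers import decode, encode, kmer_codes, revcomp_codes
from .io import Read

logger = logging.getLogger(__name__)

#: minimum soft-clip length that counts as structural-break evidence
CLIP_MIN_LEN = 20

_READ_CONSUMING = {"M", "X", "=", "I", "S"}
_REF_CONSUMING = {"M", "X", "=", "D"}


@dataclass(frozen=True)
class MapperParams:
    """Tunables of the internal mapper.

    ``max_gap`` is the largest single indel spanned within one alignment;
    ``None`` means half the read length, so 250 bp reads span gaps up to
    125 bp and are clipped at anything longer.
    """

    seed_k: int = 15
    max_gap: int | None = None
    min_identity: float = 0.90
    anchor_min: int = 30
    match_score: int = 8
    mismatch_penalty: int = 9
    gap_open: int = 16
    gap_extend: int = 1
    seed_stride: int = 11
    max_seed_hits: int = 64
    max_candidates: int = 2

    def __post_init__(self):
        if self.seed_k < 11:
            raise ValueError("seed_k must be >= 11")
        if self.max_gap is not None and self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")

    def gap_limit(self, read_length: int) -> int:
        return self.max_gap if self.max_gap is not None else read_length // 2


@dataclass
class AlignmentRecord:
    """Primary placement of one read on one reference sequence."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: list[tuple[str, int]]
    identity: float
    score: int
    read_seq: str = ""  # oriented to the forward reference strand

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0


@dataclass
class CoverageProfile:
    """Per-base read depth plus structural-evidence tracks."""

    ref_id: str
    depth: np.ndarray
    span_depth: np.ndarray
    clips: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class Pileup:
    """Per-column allele counts: A/C/G/T/deletion, plus insertion evidence."""

    ref_id: str
    base_counts: np.ndarray            # (L, 5) int32
    insertions: dict                   # pos -> {inserted string: count}
    junction_depth: np.ndarray         # alignments covering both pos and pos+1

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1)


class ReferenceIndex:
    """Sorted exact k-mer index over one or more reference sequences."""

    #: spacer between concatenated sequences; long enough that no diagonal
    #: band can bridge two sequences
    _SPACER = 2048

    def __init__(self, refs, seed_k: int = 15):
        if hasattr(refs, "accession"):  # a refdb.ReferenceGenome
            refs = [(f"{refs.accession}", s) for s in refs.sequences] \
                if len(refs.sequences) == 1 else \
                [(f"{refs.accession}/{i}", s) for i, s in enumerate(refs.sequences)]
        self.seed_k = seed_k
        self.ref_ids = [r[0] for r in refs]
        self.ref_codes = [encode(r[1]) for r in refs]
        self.lengths = np.array([len(c) for c in self.ref_codes])
        starts = []
        pos = 0
        parts = []
        spacer = np.full(self._SPACER, 4, dtype=np.uint8)
        for c in self.ref_codes:
            starts.append(pos)
            parts.append(c)
            parts.append(spacer)
            pos += len(c) + self._SPACER
        self.starts = np.array(starts, dtype=np.int64)
        self.concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        kmers, valid = kmer_codes(self.concat, seed_k)
        positions = np.nonzero(valid)[0]
        kmers = kmers[valid]
        order = np.argsort(kmers, kind="stable")
        self._sorted_kmers = kmers[order]
        self._sorted_pos = positions[order]

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._sorted_kmers, query_codes, side="left")
        hi = np.searchsorted(self._sorted_kmers, query_codes, side="right")
        return lo, hi

    def ref_of(self, global_pos: int) -> int:
        return int(np.searchsorted(self.starts, global_pos, side="right") - 1)


def as_index(reference, seed_k: int = 15) -> ReferenceIndex:
    if isinstance(reference, ReferenceIndex):
        return reference
    if isinstance(reference, tuple):
        reference = [reference]
    return ReferenceIndex(reference, seed_k=seed_k)


def _seed_hits(index: ReferenceIndex, kmers: np.ndarray, valid: np.ndarray,
               stride: int, max_hits: int):
    """(offset, global_position) seed matches of one oriented read.

    ``kmers``/``valid`` are the read's precomputed k-mer codes and validity.
    """
    if len(kmers) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    offs = np.arange(0, len(kmers), stride)
    if offs[-1] != len(kmers) - 1:
        offs = np.append(offs, len(kmers) - 1)
    offs = offs[valid[offs]]
    if len(offs) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lo, hi = index.lookup(kmers[offs])
    counts = np.minimum(hi - lo, max_hits)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    out_off = np.repeat(offs, counts)
    idx = np.repeat(lo, counts) + (np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts))
    gpos = index._sorted_pos[idx]
    return out_off, gpos


def _clusters(offsets: np.ndarray, gpos: np.ndarray, band: int):
    """Group seed hits into diagonal bands.

    Returns (support, dlo, dhi, hit) rows where ``hit`` is one seed position
    inside the reference (used to resolve which reference the band belongs
    to; the diagonal itself may fall before the reference start for reads
    overhanging an edge).
    """
    if len(offsets) == 0:
        return []
    diags = gpos - offsets
    order = np.argsort(diags, kind="stable")
    diags = diags[order]
    offs = offsets[order]
    splits = np.nonzero(np.diff(diags) > band)[0] + 1
    out = []
    for chunk_d, chunk_o in zip(np.split(diags, splits), np.split(offs, splits)):
        support = len(np.unique(chunk_o))
        out.append((support, int(chunk_d[0]), int(chunk_d[-1]),
                    int(chunk_d[0] + chunk_o[0])))
    return out


def _segment_stats(qcodes, tcodes, qb, tb, ops, params, max_gap):
    """Split a DP cigar at over-long gaps; score each segment.

    Returns list of dicts with keys ops/qs/qe/ts/te/matches/mismatches/
    gap_events/score, coordinates relative to qcodes/tcodes.
    """
    segments = []
    cur = {"ops": [], "qs": qb, "ts": tb, "matches": 0, "mismatches": 0,
           "gap_events": 0, "gap_cost": 0}
    q, t = qb, tb

    def close(end_q, end_t):
        # trim leading/trailing gap ops that splitting may have exposed
        ops_ = cur["ops"]
        while ops_ and ops_[0][0] in "ID":
            op, l = ops_.pop(0)
            cur["gap_events"] -= 1
            cur["gap_cost"] -= params.gap_open + params.gap_extend * l
            if op == "I":
                cur["qs"] += l
            else:
                cur["ts"] += l
        while ops_ and ops_[-1][0] in "ID":
            op, l = ops_.pop()
            cur["gap_events"] -= 1
            cur["gap_cost"] -= params.gap_open + params.gap_extend * l
            if op == "I":
                end_q -= l
            else:
                end_t -= l
        if ops_:
            cur["qe"] = end_q
            cur["te"] = end_t
            cur["score"] = (params.match_score * cur["matches"]
                            - params.mismatch_penalty * cur["mismatches"]
                            - cur["gap_cost"])
            segments.append(dict(cur))

    for op, l in ops:
        if op == "M":
            mism = int(np.count_nonzero(
                (qcodes[q:q + l] != tcodes[t:t + l]) | (qcodes[q:q + l] > 3)))
            cur["matches"] += l - mism
            cur["mismatches"] += mism
            cur["ops"].append(("M", l))
            q += l
            t += l
        elif op in "ID":
            if l > max_gap:
                close(q, t)
                if op == "I":
                    q += l
                else:
                    t += l
                cur = {"ops": [], "qs": q, "ts": t, "matches": 0,
                       "mismatches": 0, "gap_events": 0, "gap_cost": 0}
            else:
                cur["gap_events"] += 1
                cur["gap_cost"] += params.gap_open + params.gap_extend * l
                cur["ops"].append((op, l))
                if op == "I":
                    q += l
                else:
                    t += l
    close(q, t)
    return segments


def _max_subarray(scores: np.ndarray) -> tuple[int, int, int]:
    """Best-sum contiguous segment (sum, start, end); first on ties."""
    cs = np.concatenate(([0], np.cumsum(scores)))
    runmin = np.minimum.accumulate(cs[:-1])
    diffs = cs[1:] - runmin
    end = int(np.argmax(diffs))
    start = int(np.argmin(cs[:end + 1]))
    return int(diffs[end]), start, end + 1


def _ungapped_candidate(index, rcodes, diag, params, hit):
    """Best ungapped (clipped) alignment of a read on one diagonal.

    Substitution-only placements never benefit from gaps, so the best local
    alignment on a single seeded diagonal is the maximum-scoring contiguous
    run of the match/mismatch score vector.  Returns the same tuple shape as
    :func:`_align_candidate` or None.
    """
    L = len(rcodes)
    ref_idx = index.ref_of(hit)
    ref_lo = int(index.starts[ref_idx])
    ref_hi = ref_lo + int(index.lengths[ref_idx])
    t0 = max(diag, ref_lo)
    t1 = min(diag + L, ref_hi)
    if t1 - t0 < params.anchor_min:
        return None
    q0 = t0 - diag
    qslice = rcodes[q0:q0 + (t1 - t0)]
    m = (qslice == index.concat[t0:t1]) & (qslice < 4)
    scores = np.where(m, params.match_score, -params.mismatch_penalty)
    score, ks, ke = _max_subarray(scores)
    if score <= 0:
        return None
    matches = int(np.count_nonzero(m[ks:ke]))
    identity = _passes(params, matches, (ke - ks) - matches, 0)
    if identity is None:
        return None
    return (score, t0 + ks, t0 + ke, q0 + ks, q0 + ke,
            [("M", ke - ks)], identity)


def _passes(params, matches, mismatches, gap_events):
    aligned = matches + mismatches
    if aligned < params.anchor_min:
        return None
    identity = matches / (aligned + gap_events)
    if identity < params.min_identity:
        return None
    return identity


def _align_candidate(index, rcodes, cluster, params, max_gap):
    """Align oriented read codes against the window of one diagonal cluster.

    Returns (score, global_t_start, global_t_end, q_start, q_end, ops,
    identity) for an alignment passing the identity/anchor gates, else None.

    The DP runs with a cheap gap-extension cost so that real structural gaps
    up to ``max_gap`` can be spanned; in random sequence that lets the local
    alignment drift past the true ends, which the identity gate detects.  On
    gate failure the DP is retried with expensive gap extension, which yields
    the clean clipped alignment instead.
    """
    support, dlo, dhi, hit = cluster
    L = len(rcodes)
    ref_idx = index.ref_of(hit)
    ref_lo = int(index.starts[ref_idx])
    ref_hi = ref_lo + int(index.lengths[ref_idx])
    pad = max_gap + 16
    wlo = max(dlo - pad, ref_lo)
    whi = min(dhi + L + pad, ref_hi)
    if whi - wlo < params.anchor_min:
        return None
    window = index.concat[wlo:whi]
    for gap_extend in (params.gap_extend, params.match_score):
        score, qb, qe, tb, te, ops = local_align(
            rcodes, window, params.match_score, -params.mismatch_penalty,
            params.gap_open, gap_extend)
        if score <= 0 or not ops:
            return None
        segments = _segment_stats(rcodes, window, qb, tb, ops, params, max_gap)
        if not segments:
            continue
        best = max(segments, key=lambda s: (s["score"], -s["qs"]))
        identity = _passes(params, best["matches"], best["mismatches"],
                           best["gap_events"])
        if identity is not None:
            return (best["score"], wlo + best["ts"], wlo + best["te"],
                    best["qs"], best["qe"], best["ops"], identity)
    return None


_ALPHABET = set("ACGTNacgtn")


def map_reads(reads, reference, params: MapperParams | None = None) -> list[AlignmentRecord]:
    """Map reads against a reference; at most one primary alignment per read.

    ``reference`` may be a :class:`ReferenceIndex`, a ``(ref_id, seq)`` tuple,
    a list of such tuples, or a refdb genome record.  Mates of a pair are
    mapped independently.
    """
    params = params or MapperParams()
    index = as_index(reference, params.seed_k)
    records: list[AlignmentRecord] = []
    n_skipped = 0
    usable: list[Read] = []
    fwd_codes: list[np.ndarray] = []
    for read in reads:
        if set(read.seq) - _ALPHABET:
            n_skipped += 1
            continue
        if len(read.seq) >= params.seed_k:
            usable.append(read)
            fwd_codes.append(encode(read.seq))
    if n_skipped:
        logger.warning("skipped %d reads with non-ACGTN characters", n_skipped)
    if not usable:
        return records
    # batch k-mer extraction over all reads at once (separator-joined)
    rc_codes = [revcomp_codes(c) for c in fwd_codes]
    sep = np.array([4], dtype=np.uint8)
    k = params.seed_k
    kmf, vf = kmer_codes(np.concatenate(
        [p for c in fwd_codes for p in (c, sep)][:-1]), k)
    kmr, vr = kmer_codes(np.concatenate(
        [p for c in rc_codes for p in (c, sep)][:-1]), k)
    pos = 0
    for read, fwd, rc in zip(usable, fwd_codes, rc_codes):
        L = len(fwd)
        lo, hi = pos, pos + L - k + 1
        rec = _map_one(read, index, params,
                       ((fwd, kmf[lo:hi], vf[lo:hi]),
                        (rc, kmr[lo:hi], vr[lo:hi])))
        pos += L + 1
        if rec is not None:
            records.append(rec)
    return records


def _map_one(read: Read, index: ReferenceIndex, params: MapperParams, strands):
    (fwd, kmf, vf), (rc, kmr, vr) = strands
    L = len(fwd)
    max_gap = params.gap_limit(L)
    band = max_gap + 16
    candidates = []  # (support, strand_order, dlo, dhi, seed_hit, strand, codes)
    for strand, codes, km, vm in (("+", fwd, kmf, vf), ("-", rc, kmr, vr)):
        offs, gpos = _seed_hits(index, km, vm, params.seed_stride,
                                params.max_seed_hits)
        for support, dlo, dhi, seed_hit in _clusters(offs, gpos, band):
            candidates.append((support, 0 if strand == "+" else 1, dlo, dhi,
                               seed_hit, strand, codes))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best = None
    for support, sorder, dlo, dhi, seed_hit, strand, codes in \
            candidates[:params.max_candidates]:
        if dlo == dhi:
            hit = _ungapped_candidate(index, codes, dlo, params, seed_hit)
        else:
            hit = _align_candidate(index, codes, (support, dlo, dhi, seed_hit),
                                   params, max_gap)
        if hit is None:
            continue
        score, gts, gte, qs, qe, ops, identity = hit
        ref_idx = index.ref_of(gts)
        key = (-score, gts - int(index.starts[ref_idx]), ref_idx, sorder)
        if best is None or key < best[0]:
            best = (key, (score, gts, gte, qs, qe, ops, identity, strand, codes))
    if best is None:
        return None
    score, gts, gte, qs, qe, ops, identity, strand, codes = best[1]
    ref_idx = index.ref_of(gts)
    start = int(index.starts[ref_idx])
    cigar = list(ops)
    if qs > 0:
        cigar.insert(0, ("S", qs))
    if qe < L:
        cigar.append(("S", L - qe))
    return AlignmentRecord(
        read_id=read.id,
        ref_id=index.ref_ids[ref_idx],
        ref_start=gts - start,
        ref_end=gte - start,
        strand=strand,
        cigar=cigar,
        identity=identity,
        score=score,
        read_seq=decode(codes),
    )


def compute_coverage(alignments, ref_length: int, anchor_min: int = 30,
                     ref_id: str = "") -> CoverageProfile:
    """Per-base depth, spanning depth, and clip-evidence counts.

    ``depth[i]`` counts alignments whose reference span covers i (deleted
    reference columns included, so sum(depth) equals the total number of
    reference-consuming cigar bases).  ``span_depth[i]`` additionally requires
    at least ``anchor_min`` aligned reference bases on each side of i within
    the same alignment.  ``clips[i]`` counts soft-clips of >= CLIP_MIN_LEN
    bases whose clip point falls at i.
    """
    depth = np.zeros(ref_length + 1, dtype=np.int64)
    span = np.zeros(ref_length + 1, dtype=np.int64)
    clips = np.zeros(ref_length, dtype=np.int64)
    for a in alignments:
        if a.ref_start < 0 or a.ref_end > ref_length:
            raise ValueError(
                f"alignment {a.read_id} [{a.ref_start},{a.ref_end}) exceeds "
                f"reference bounds (length {ref_length})")
        depth[a.ref_start] += 1
        depth[a.ref_end] -= 1
        s, e = a.ref_start + anchor_min, a.ref_end - anchor_min
        if e > s:
            span[s] += 1
            span[e] -= 1
        if a.left_clip >= CLIP_MIN_LEN:
            clips[a.ref_start] += 1
        if a.right_clip >= CLIP_MIN_LEN:
            clips[min(a.ref_end, ref_length - 1)] += 1
    return CoverageProfile(
        ref_id=ref_id,
        depth=np.cumsum(depth[:-1]),
        span_depth=np.cumsum(span[:-1]),
        clips=clips,
    )


def pileup(alignments, reference) -> Pileup:
    """Column-wise allele counts from primary alignments on one reference.

    ``reference`` is ``(ref_id, seq)`` or a plain sequence string.  Alignments
    must carry their oriented read sequence (``read_seq``).
    """
    if isinstance(reference, tuple):
        ref_id, seq = reference
    else:
        ref_id, seq = "", reference
    L = len(seq)
    counts = np.zeros((L, 5), dtype=np.int32)
    insertions: dict[int, dict[str, int]] = {}
    junction = np.zeros(L + 1, dtype=np.int64)
    for a in alignments:
        codes = encode(a.read_seq)
        q = 0
        t = a.ref_start
        for op, l in a.cigar:
            if op in ("M", "X", "="):
                block = np.minimum(codes[q:q + l], 4)
                np.add.at(counts, (np.arange(t, t + l), block), 1)
                q += l
                t += l
            elif op == "I":
                ins = a.read_seq[q:q + l]
                pos = t - 1
                if pos >= 0:
                    insertions.setdefault(pos, {})
                    insertions[pos][ins] = insertions[pos].get(ins, 0) + 1
                q += l
            elif op == "D":
                counts[t:t + l, 4] += 1
                t += l
            elif op == "S":
                q += l
        if a.ref_end - a.ref_start >= 2:
            junction[a.ref_start] += 1
            junction[a.ref_end - 1] -= 1
    return Pileup(ref_id=ref_id, base_counts=counts, insertions=insertions,
                  junction_depth=np.cumsum(junction[:-1]))


def write_sam(path, alignments, refs) -> None:
    """Minimal valid SAM export of primary alignments (debugging aid)."""
    refs = [refs] if isinstance(refs, tuple) else list(refs)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for rid, seq in refs:
            fh.write(f"@SQ\tSN:{rid}\tLN:{len(seq)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            cig = "".join(f"{l}{op}" for op, l in a.cigar)
            fh.write(f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.ref_start + 1}\t60\t"
                     f"{cig}\t*\t0\t0\t{a.read_seq}\t*\n")
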