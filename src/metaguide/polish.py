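"""Pileup-majority consensus polishing of contigs.

Contigs produced by coverage-break extraction carry reference sequence; the
polisher replaces it column by column with the read consensus so the output
reflects the sampled organism rather than the guide.  An edit is applied only
where coverage is at least ``min_depth`` and the plurality allele strictly
exceeds ``min_fraction`` (exact ties keep the reference base).  A single
polishing round is used; every applied edit is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kmers import encode
from .mapping import Pileup


@dataclass(frozen=True)
class PolishParams:
    min_depth: int = 2
    min_fraction: float = 0.6
    max_indel: int = 50

    def __post_init__(self):
        if not self.min_fraction > 0.5:
            raise ValueError("min_fraction must exceed 0.5 (majority semantics)")


@dataclass
class PolishEdit:
    position: int  # 0-based coordinate on the unpolished contig
    type: str      # substitution | insertion | deletion
    ref_allele: str
    alt_allele: str
    depth: int
    support: int


def polish_contig(interval: tuple[int, int], reference: str, pile: Pileup,
                  params: PolishParams | None = None
                  ) -> tuple[str, list[PolishEdit]]:
    """Majority-consensus sequence for one contig interval.

    ``interval`` is half-open on the reference the pileup was built from.
    Returns the polished sequence and the applied edits (contig coordinates).
    """
    params = params or PolishParams()
    s, e = interval
    if e > len(reference) or pile.base_counts.shape[0] != len(reference):
        raise ValueError("pileup/contig length mismatch")
    counts = pile.base_counts[s:e]
    depth = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    support = counts[np.arange(len(counts)), best]
    ref_codes = np.minimum(encode(reference[s:e]), 4)
    editable = (depth >= params.min_depth) \
        & (support > params.min_fraction * depth) \
        & (best != ref_codes)
    edits: list[PolishEdit] = []
    pieces: list[str] = []
    cursor = 0
    bases = "ACGTN"

    def flush(upto):
        nonlocal cursor
        if upto > cursor:
            pieces.append(reference[s + cursor:s + upto])
        cursor = upto

    events = []  # (contig position, kind, payload)
    for pos in np.nonzero(editable)[0]:
        events.append((int(pos), 0, None))
    # insertions keyed by the reference position they follow
    for rpos in sorted(p for p in pile.insertions if s <= p < e - 1):
        spanning = int(pile.junction_depth[rpos])
        if spanning < params.min_depth:
            continue
        ins_counts = pile.insertions[rpos]
        alt = min(ins_counts, key=lambda k: (-ins_counts[k], k))
        cnt = ins_counts[alt]
        if cnt > params.min_fraction * spanning and len(alt) <= params.max_indel:
            events.append((rpos - s, 1, (alt, spanning, cnt)))
    events.sort()
    for pos, kind, payload in events:
        if kind == 0:
            flush(pos)
            cursor = pos + 1
            ref_base = reference[s + pos]
            d, sup = int(depth[pos]), int(support[pos])
            if best[pos] == 4:
                edits.append(PolishEdit(pos, "deletion", ref_base, "", d, sup))
            else:
                alt = bases[best[pos]]
                pieces.append(alt)
                edits.append(PolishEdit(pos, "substitution", ref_base, alt, d, sup))
        else:
            alt, spanning, cnt = payload
            flush(pos + 1)
            pieces.append(alt)
            edits.append(PolishEdit(pos, "insertion", "", alt, spanning, cnt))
    flush(e - s)
    return "".join(pieces), edits


def write_edit_report(path, rows: list[tuple[str, PolishEdit]]) -> None:
    """TSV report of applied edits: (contig_id, edit) pairs."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\ttype\tref\talt\tdepth\tsupport\n")
        for contig_id, ed in rows:
            fh.write(f"{contig_id}\t{ed.position}\t{ed.type}\t"
                     f"{ed.ref_allele}\t{ed.alt_allele}\t{ed.depth}\t{ed.support}\n")
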