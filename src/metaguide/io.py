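"""Sequence file I/O: FASTA/FASTQ (optionally gzipped) via Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO


class Read(NamedTuple):
    """A sequencing read (mates of a pair are independent reads)."""

    id: str
    seq: str


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, sequence)`` pairs (uppercased)."""
    out = []
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                seq = str(rec.seq).upper()
                if not seq:
                    raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
                out.append((rec.id, seq))
    except ValueError as exc:
        raise ValueError(f"unparseable FASTA {path}: {exc}") from exc
    if not out:
        raise ValueError(f"no FASTA records parsed from {path}")
    return out


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(*paths) -> list[Read]:
    """Parse one or more FASTQ files (optionally .gz) into a flat read list."""
    reads: list[Read] = []
    for path in paths:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(Read(rec.id, str(rec.seq).upper()))
    return reads


def write_fastq(path, reads: Iterable[Read]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")

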