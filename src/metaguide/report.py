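"""Assembly metrics, standard-format writers, and output orchestration.

NGx here is genome-size-aware contiguity: the largest contig length c such
that contigs of length >= c together strictly exceed x% of the (known)
genome size; undefined (NA) when the assembly itself does not reach x%.
Representativeness is the fraction of input reads with an accepted primary
alignment to the final contigs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .assembly import SampleAssembly
from .io import write_fasta, write_fastq
from .mapping import MapperParams, ReferenceIndex, map_reads
from .polish import write_edit_report


def ngx(contig_lengths, genome_size: int, x: float):
    """NG(x): largest c with sum(lengths >= c) > x% of genome_size, else None.

    ``x`` is a percentage in (0, 100).  Returns None (NA) when the total
    assembly length does not exceed the x% target.
    """
    if not 0 < x < 100:
        raise ValueError("x must lie in (0, 100)")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    target = x / 100.0 * genome_size
    lengths = sorted(contig_lengths, reverse=True)
    cum = 0
    for c in lengths:
        cum += c
        if cum > target:
            return c
    return None


def fraction_reads_mapped(reads, contigs,
                          mapper_params: MapperParams | None = None) -> float:
    """Fraction of reads with an accepted primary alignment to the contigs.

    ``contigs`` is a list of (contig_id, sequence); returns 0.0 when either
    the read set or the contig set is empty.
    """
    if not reads or not contigs:
        return 0.0
    mapper_params = mapper_params or MapperParams()
    index = ReferenceIndex(list(contigs), mapper_params.seed_k)
    alignments = map_reads(reads, index, mapper_params)
    return len({a.read_id for a in alignments}) / len(reads)


def assembly_stats(sample: SampleAssembly) -> pd.DataFrame:
    """Per-reference contiguity/coverage table plus a sample-level row."""
    rows = []
    for ca in sample.clusters:
        for res in ca.results:
            lens = [len(c.sequence) for c in res.contigs]
            rows.append({
                "cluster": ca.cluster.cluster_id,
                "reference": res.ref_accession,
                "n_contigs": len(lens),
                "cum_length": res.cum_length,
                "longest": res.longest,
                "NG25": ngx(lens, res.ref_length, 25) if lens else None,
                "NG50": ngx(lens, res.ref_length, 50) if lens else None,
                "breadth_of_ref": round(res.breadth_of_ref, 4),
                "genomes_used": len(ca.results),
            })
    total = sum(r["cum_length"] for r in rows)
    rows.append({"cluster": "sample", "reference": "*",
                 "n_contigs": sum(r["n_contigs"] for r in rows),
                 "cum_length": total, "longest": max((r["longest"] for r in rows),
                                                     default=0),
                 "NG25": None, "NG50": None, "breadth_of_ref": None,
                 "genomes_used": sum(len(ca.results) for ca in sample.clusters)})
    return pd.DataFrame(rows)


def agp_rows(result) -> list[list]:
    """AGP v2.1 rows (one object per reference) for one guided-pass result.

    W rows place contigs (object coordinates are the 1-based inclusive
    pre-polish reference span; component coordinates cover the polished
    contig); U rows carry the uncovered gap length between consecutive
    contigs (gap_type scaffold, linkage no).
    """
    rows = []
    by_ref: dict[str, list] = {}
    for c in result.contigs:
        by_ref.setdefault(c.ref_accession, []).append(c)
    for ref_id in sorted(by_ref):
        contigs = sorted(by_ref[ref_id], key=lambda c: c.ref_start)
        part = 0
        prev_end = None
        for c in contigs:
            if prev_end is not None and c.ref_start > prev_end:
                part += 1
                rows.append([ref_id, prev_end + 1, c.ref_start, part, "U",
                             c.ref_start - prev_end, "scaffold", "no", "na"])
            part += 1
            rows.append([ref_id, c.ref_start + 1, c.ref_end, part, "W",
                         c.contig_id, 1, len(c.sequence), "+"])
            prev_end = c.ref_end
    return rows


def write_agp(path, results) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for res in results:
            for row in agp_rows(res):
                fh.write("\t".join(str(x) for x in row) + "\n")


def validate_agp(path) -> None:
    """Strict column/coordinate validation of an AGP file written here.

    Raises ValueError on the first violation.  Checks: 9 columns; integer
    coordinates with beg <= end; per-object part numbers sequential from 1;
    rows coordinate-contiguous within an object; U rows internally
    consistent (span == gap length, gap_type/linkage fields valid).
    """
    state: dict[str, tuple[int, int]] = {}  # object -> (last part, last end)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            obj, beg, end, part, comp_type = cols[0], int(cols[1]), int(cols[2]), \
                int(cols[3]), cols[4]
            if beg > end or beg < 1:
                raise ValueError(f"line {lineno}: bad object span {beg}-{end}")
            last_part, last_end = state.get(obj, (0, None))
            if part != last_part + 1:
                raise ValueError(f"line {lineno}: part number {part} not sequential")
            if last_end is not None and beg != last_end + 1:
                raise ValueError(f"line {lineno}: object coordinates not contiguous")
            if comp_type == "W":
                cbeg, cend = int(cols[6]), int(cols[7])
                if cbeg != 1 or cend < cbeg:
                    raise ValueError(f"line {lineno}: bad component span")
                if cols[8] not in "+-?":
                    raise ValueError(f"line {lineno}: bad orientation {cols[8]!r}")
            elif comp_type == "U":
                if int(cols[5]) != end - beg + 1:
                    raise ValueError(f"line {lineno}: gap length != object span")
                if cols[6] != "scaffold" or cols[7] not in ("no", "yes"):
                    raise ValueError(f"line {lineno}: bad gap descriptor")
            else:
                raise ValueError(f"line {lineno}: unsupported component type "
                                 f"{comp_type!r}")
            state[obj] = (part, end)


def write_outputs(sample: SampleAssembly, reads, out_dir,
                  write_leftovers: bool = True) -> dict[str, Path]:
    """Write the standard output bundle for one assembled sample.

    Files: contigs FASTA, AGP (v2.1 dialect), polish-edit report TSV,
    leftover-reads FASTQ, per-reference stats TSV, reference accession list,
    and the run log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out / "contigs.fasta",
        "agp": out / "contigs.agp",
        "edits": out / "polish_edits.tsv",
        "stats": out / "assembly_stats.tsv",
        "references": out / "references_used.txt",
        "log": out / "run_log.txt",
    }
    contigs = [(c.contig_id, c.sequence) for _, _, c in sample.all_contigs]
    write_fasta(paths["contigs"], contigs)
    write_agp(paths["agp"], [res for ca in sample.clusters for res in ca.results])
    write_edit_report(paths["edits"],
                      [(c.contig_id, ed) for _, _, c in sample.all_contigs
                       for ed in c.edits])
    assembly_stats(sample).to_csv(paths["stats"], sep="\t", index=False,
                                  na_rep="NA")
    refs = sorted({res.ref_accession for ca in sample.clusters
                   for res in ca.results})
    paths["references"].write_text("".join(a + "\n" for a in refs))
    paths["log"].write_text("".join(line + "\n" for line in sample.log))
    if write_leftovers:
        paths["leftovers"] = out / "leftover_reads.fastq"
        leftover = set(sample.leftover_read_ids)
        write_fastq(paths["leftovers"], [r for r in reads if r.id in leftover])
    return paths
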