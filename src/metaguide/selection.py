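"""Sample-specific reference selection by universal-marker coverage.

Reads are mapped against marker-cluster representatives only; each
representative's breadth of coverage propagates unchanged to every member
marker.  A genome is selected when at least ``min_marker_fraction`` (default
75%, inclusive) of the marker families annotated in it are covered, where a
family counts as covered only if breadth strictly exceeds ``min_breadth``
(default 90%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import MapperParams, ReferenceIndex, compute_coverage, map_reads
from .refdb import MarkerCatalog, ReferenceDatabase


@dataclass(frozen=True)
class SelectionParams:
    min_marker_fraction: float = 0.75
    min_breadth: float = 0.90
    #: fold-coverage band the marker screen is expected to detect (QC note
    #: only; genomes covered below ~1x rarely clear the breadth threshold)
    expected_marker_depth_range: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self):
        for f in (self.min_marker_fraction, self.min_breadth):
            if not 0 < f <= 1:
                raise ValueError("selection fractions must be in (0, 1]")


@dataclass
class MarkerCoverage:
    breadth: float
    mean_depth: float


@dataclass
class MarkerCoverageTable:
    """Breadth/depth per (genome accession, marker family).

    Families without an annotated marker in a genome are absent from the
    table (missing, not zero).
    """

    entries: dict[tuple[str, int], MarkerCoverage] = field(default_factory=dict)

    def breadth(self, accession: str, family: int) -> float | None:
        cov = self.entries.get((accession, family))
        return cov.breadth if cov else None


def screen_markers(reads, database: ReferenceDatabase,
                   params: SelectionParams | None = None,
                   mapper_params: MapperParams | None = None,
                   catalog: MarkerCatalog | None = None) -> MarkerCoverageTable:
    """Map reads to marker representatives; propagate coverage to members."""
    catalog = catalog or database.catalog
    table = MarkerCoverageTable()
    if not catalog.representatives or not reads:
        return table
    refs = [(m.marker_id, m.sequence) for m in catalog.representatives]
    mapper_params = mapper_params or MapperParams()
    index = ReferenceIndex(refs, mapper_params.seed_k)
    alignments = map_reads(reads, index, mapper_params)
    by_rep: dict[str, list] = {}
    for a in alignments:
        by_rep.setdefault(a.ref_id, []).append(a)
    rep_cov: dict[str, MarkerCoverage] = {}
    for rep in catalog.representatives:
        alns = by_rep.get(rep.marker_id, [])
        if alns:
            depth = compute_coverage(alns, rep.length, anchor_min=0,
                                     ref_id=rep.marker_id).depth
            breadth = float(np.count_nonzero(depth)) / rep.length
            mean_depth = float(depth.mean())
        else:
            breadth, mean_depth = 0.0, 0.0
        rep_cov[rep.marker_id] = MarkerCoverage(breadth, mean_depth)
    for rep_id, members in catalog.member_map.items():
        cov = rep_cov.get(rep_id)
        if cov is None:
            continue
        for mid in members:
            m = database.markers[mid]
            key = (m.genome_accession, m.family)
            prev = table.entries.get(key)
            # a genome normally has one marker per family; keep the best
            if prev is None or cov.breadth > prev.breadth:
                table.entries[key] = cov
    return table


def select_references(table: MarkerCoverageTable, database: ReferenceDatabase,
                      params: SelectionParams | None = None
                      ) -> list[tuple[str, int]]:
    """Genomes whose covered-family fraction clears the selection threshold.

    Returns ``(accession, covered_family_count)`` sorted by covered count
    descending, accession ascending.  The denominator is the number of
    families annotated in that genome, and "covered" means breadth strictly
    greater than ``min_breadth``.
    """
    params = params or SelectionParams()
    selected = []
    for acc in sorted(database.genomes):
        genome = database.genomes[acc]
        families = {database.markers[mid].family for mid in genome.marker_ids}
        if not families:
            continue
        covered = sum(
            1 for f in families
            if (b := table.breadth(acc, f)) is not None and b > params.min_breadth)
        if covered / len(families) >= params.min_marker_fraction:
            selected.append((acc, covered))
    selected.sort(key=lambda t: (-t[1], t[0]))
    return selected


def selection_report(table: MarkerCoverageTable, database: ReferenceDatabase,
                     params: SelectionParams | None = None) -> str:
    """TSV report of per-genome marker coverage and selection status."""
    params = params or SelectionParams()
    chosen = {acc for acc, _ in select_references(table, database, params)}
    lines = ["genome\tfamilies_annotated\tfamilies_covered\tfraction\t"
             "selected\tmean_marker_depth"]
    for acc in sorted(database.genomes):
        genome = database.genomes[acc]
        families = {database.markers[mid].family for mid in genome.marker_ids}
        if not families:
            lines.append(f"{acc}\t0\t0\t0.0000\tFalse\t0.00")
            continue
        covered = sum(
            1 for f in families
            if (b := table.breadth(acc, f)) is not None and b > params.min_breadth)
        depths = [table.entries[(acc, f)].mean_depth for f in families
                  if (acc, f) in table.entries]
        mean_depth = float(np.mean(depths)) if depths else 0.0
        lines.append(f"{acc}\t{len(families)}\t{covered}\t"
                     f"{covered / len(families):.4f}\t{acc in chosen}\t"
                     f"{mean_depth:.2f}")
    return "\n".join(lines) + "\n"
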