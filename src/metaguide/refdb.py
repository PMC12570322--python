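"""Reference database: genome store, marker catalog, sketches and k-mer sets.

A database is built from genome FASTA files plus a marker FASTA whose headers
carry ``marker_id|genome_accession|family`` (family 1..40, the universal
single-copy marker families).  Markers of each family are clustered at 99%
global identity and only cluster representatives are screened against reads;
coverage propagates to members through the catalog.

Sketches (bottom-s MinHash, k=21, s=1000) support ANI estimation and
containment ranking; canonical 28-mer sets support cluster prioritisation.
All hashing uses a fixed recorded seed so databases are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from ._kmers import DEFAULT_HASH_SEED, code_to_kmer, kmer_code_set, sketch_hashes
from .io import read_fasta, write_fasta

DB_FORMAT_VERSION = 1


@dataclass
class ReferenceGenome:
    accession: str
    sequences: list[str]
    marker_ids: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def __post_init__(self):
        if self.total_length <= 0:
            raise ValueError(f"genome {self.accession!r} has no sequence")


@dataclass
class MarkerGene:
    marker_id: str
    family: int
    genome_accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        if not 1 <= self.family <= 40:
            raise ValueError(
                f"marker {self.marker_id!r}: family {self.family} outside 1..40")


@dataclass
class MarkerCatalog:
    """Per-family 99%-identity clustering of marker genes."""

    representatives: list[MarkerGene]
    member_map: dict[str, list[str]]
    identity_threshold: float = 0.99

    def representative_of(self, marker_id: str) -> str:
        for rep, members in self.member_map.items():
            if marker_id in members:
                return rep
        raise KeyError(marker_id)


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of canonical k-mers."""

    k: int
    s: int
    hashes: np.ndarray  # sorted ascending uint64, length <= s
    source_length: int

    def jaccard(self, other: "Sketch") -> float:
        if self.k != other.k:
            raise ValueError(f"sketch k mismatch: {self.k} != {other.k}")
        if len(self.hashes) == 0 or len(other.hashes) == 0:
            return 0.0
        union = np.union1d(self.hashes, other.hashes)[: max(self.s, other.s)]
        inter = np.intersect1d(self.hashes, other.hashes, assume_unique=True)
        shared = np.intersect1d(union, inter, assume_unique=True)
        return len(shared) / len(union)

    def containment_in(self, hash_set: np.ndarray) -> float:
        """Fraction of this sketch's hashes present in a sorted hash array."""
        if len(self.hashes) == 0 or len(hash_set) == 0:
            return 0.0
        idx = np.minimum(np.searchsorted(hash_set, self.hashes),
                         len(hash_set) - 1)
        found = np.count_nonzero(hash_set[idx] == self.hashes)
        return float(found) / len(self.hashes)


@dataclass
class KmerSet:
    """Set of distinct canonical k-mers, stored packed for fast intersection."""

    k: int
    codes: np.ndarray  # sorted unique uint64

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def kmers(self) -> frozenset[str]:
        return frozenset(code_to_kmer(c, self.k) for c in self.codes)

    def intersection_size(self, other: "KmerSet") -> int:
        if self.k != other.k:
            raise ValueError(f"k-mer set k mismatch: {self.k} != {other.k}")
        return len(np.intersect1d(self.codes, other.codes, assume_unique=True))


def sketch(seqs, k: int = 21, s: int = 1000,
           hash_seed: int = DEFAULT_HASH_SEED) -> Sketch:
    """MinHash sketch of one sequence or a list of sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    if k < 11:
        raise ValueError("sketch k must be >= 11")
    total = sum(len(x) for x in seqs)
    return Sketch(k=k, s=s, hashes=sketch_hashes(seqs, k, s, hash_seed),
                  source_length=total)


def kmer_set(seqs, k: int = 28) -> KmerSet:
    if isinstance(seqs, str):
        seqs = [seqs]
    return KmerSet(k=k, codes=kmer_code_set(seqs, k))


def alignment_identity(a: str, b: str) -> float:
    """Global alignment identity = matches / alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n, _ in _parse_cigar(res["cigar"]))
    return (cols - res["editDistance"]) / cols


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def cluster_markers(markers: list[MarkerGene],
                    identity_threshold: float = 0.99) -> MarkerCatalog:
    """Greedy per-family clustering by global identity.

    Family members are visited longest-first (ties by marker_id); each joins
    the first existing representative at >= threshold identity, else founds a
    new cluster.  Deterministic for a given input set.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    reps: list[MarkerGene] = []
    member_map: dict[str, list[str]] = {}
    families = sorted({m.family for m in markers})
    by_family = {f: sorted((m for m in markers if m.family == f),
                           key=lambda m: (-m.length, m.marker_id))
                 for f in families}
    for f in families:
        fam_reps: list[MarkerGene] = []
        for m in by_family[f]:
            placed = False
            for rep in fam_reps:
                if alignment_identity(m.sequence, rep.sequence) >= identity_threshold:
                    member_map[rep.marker_id].append(m.marker_id)
                    placed = True
                    break
            if not placed:
                fam_reps.append(m)
                member_map[m.marker_id] = [m.marker_id]
        reps.extend(fam_reps)
    return MarkerCatalog(representatives=reps, member_map=member_map,
                         identity_threshold=identity_threshold)


class ReferenceDatabase:
    """Genomes + markers + catalog + lazily built sketches and k-mer sets."""

    def __init__(self, genomes: dict[str, ReferenceGenome],
                 markers: dict[str, MarkerGene],
                 catalog: MarkerCatalog | None = None,
                 sketch_k: int = 21, sketch_s: int = 1000, kmer_k: int = 28,
                 marker_identity: float = 0.99,
                 hash_seed: int = DEFAULT_HASH_SEED):
        self.genomes = genomes
        self.markers = markers
        self.sketch_k = sketch_k
        self.sketch_s = sketch_s
        self.kmer_k = kmer_k
        self.marker_identity = marker_identity
        self.hash_seed = hash_seed
        self.catalog = catalog if catalog is not None else cluster_markers(
            list(markers.values()), marker_identity)
        self._sketches: dict[str, Sketch] = {}
        self._kmer_sets: dict[str, KmerSet] = {}

    # -- lazy per-genome structures -------------------------------------
    def genome_sketch(self, accession: str) -> Sketch:
        if accession not in self._sketches:
            g = self.genomes[accession]
            self._sketches[accession] = sketch(
                g.sequences, self.sketch_k, self.sketch_s, self.hash_seed)
        return self._sketches[accession]

    def genome_kmer_set(self, accession: str) -> KmerSet:
        if accession not in self._kmer_sets:
            g = self.genomes[accession]
            self._kmer_sets[accession] = kmer_set(g.sequences, self.kmer_k)
        return self._kmer_sets[accession]

    # -- persistence -----------------------------------------------------
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": DB_FORMAT_VERSION,
            "hash_seed": self.hash_seed,
            "sketch_k": self.sketch_k,
            "sketch_s": self.sketch_s,
            "kmer_k": self.kmer_k,
            "marker_identity": self.marker_identity,
            "genomes": {a: {"n_sequences": len(g.sequences),
                            "total_length": g.total_length,
                            "marker_ids": g.marker_ids}
                        for a, g in sorted(self.genomes.items())},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        write_fasta(out / "genomes.fasta",
                    [(f"{a}|{i}", s) for a, g in sorted(self.genomes.items())
                     for i, s in enumerate(g.sequences)])
        write_fasta(out / "markers.fasta",
                    [(f"{m.marker_id}|{m.genome_accession}|{m.family}", m.sequence)
                     for _, m in sorted(self.markers.items())])
        (out / "catalog.json").write_text(json.dumps({
            "identity_threshold": self.catalog.identity_threshold,
            "representatives": [m.marker_id for m in self.catalog.representatives],
            "member_map": self.catalog.member_map,
        }, indent=1))
        np.savez(out / "sketches.npz",
                 **{a: self.genome_sketch(a).hashes for a in sorted(self.genomes)})
        np.savez(out / "kmersets.npz",
                 **{a: self.genome_kmer_set(a).codes for a in sorted(self.genomes)})

    @classmethod
    def load(cls, db_dir) -> "ReferenceDatabase":
        db = Path(db_dir)
        manifest = json.loads((db / "manifest.json").read_text())
        if manifest["format_version"] != DB_FORMAT_VERSION:
            raise ValueError(f"unsupported database format version "
                             f"{manifest['format_version']}")
        seqs: dict[str, list[str]] = {}
        for rid, seq in read_fasta(db / "genomes.fasta"):
            acc = rid.rsplit("|", 1)[0]
            seqs.setdefault(acc, []).append(seq)
        genomes = {a: ReferenceGenome(a, seqs[a],
                                      manifest["genomes"][a]["marker_ids"])
                   for a in manifest["genomes"]}
        markers = {m.marker_id: m for m in _parse_marker_fasta(db / "markers.fasta")}
        cat = json.loads((db / "catalog.json").read_text())
        catalog = MarkerCatalog(
            representatives=[markers[i] for i in cat["representatives"]],
            member_map=cat["member_map"],
            identity_threshold=cat["identity_threshold"])
        inst = cls(genomes, markers, catalog,
                   sketch_k=manifest["sketch_k"], sketch_s=manifest["sketch_s"],
                   kmer_k=manifest["kmer_k"],
                   marker_identity=manifest["marker_identity"],
                   hash_seed=manifest["hash_seed"])
        with np.load(db / "sketches.npz") as z:
            for a in z.files:
                inst._sketches[a] = Sketch(
                    k=inst.sketch_k, s=inst.sketch_s, hashes=z[a],
                    source_length=genomes[a].total_length)
        with np.load(db / "kmersets.npz") as z:
            for a in z.files:
                inst._kmer_sets[a] = KmerSet(k=inst.kmer_k, codes=z[a])
        return inst


def _parse_marker_fasta(path) -> list[MarkerGene]:
    markers = []
    try:
        records = read_fasta(path)
    except ValueError as exc:
        if "no FASTA records" in str(exc):
            return []
        raise
    for rid, seq in records:
        parts = rid.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"marker header {rid!r} in {path} does not follow "
                f"'marker_id|genome_accession|family'")
        mid, acc, family = parts
        markers.append(MarkerGene(mid, int(family), acc, seq))
    return markers


def load_genomes(fasta_paths, marker_path=None, *, markers=None,
                 sketch_k: int = 21, sketch_s: int = 1000, kmer_k: int = 28,
                 marker_identity: float = 0.99,
                 hash_seed: int = DEFAULT_HASH_SEED) -> ReferenceDatabase:
    """Build a database from genome FASTA files and marker annotations.

    Each genome FASTA becomes one :class:`ReferenceGenome`; its accession is
    the shared prefix of its record ids (``acc`` or ``acc|i``).  Markers may
    be given as a FASTA path (header dialect ``marker_id|genome|family``) or
    as a prebuilt list of :class:`MarkerGene`.
    """
    genomes: dict[str, ReferenceGenome] = {}
    for path in ([fasta_paths] if isinstance(fasta_paths, (str, Path))
                 else fasta_paths):
        records = read_fasta(path)
        acc = records[0][0].rsplit("|", 1)[0]
        if acc in genomes:
            raise ValueError(f"duplicate genome accession {acc!r} ({path})")
        genomes[acc] = ReferenceGenome(acc, [s for _, s in records])
    if markers is None:
        markers = _parse_marker_fasta(marker_path) if marker_path else []
    marker_dict: dict[str, MarkerGene] = {}
    for m in markers:
        if m.genome_accession not in genomes:
            raise ValueError(
                f"marker {m.marker_id!r} references unknown genome "
                f"{m.genome_accession!r}")
        if m.marker_id in marker_dict:
            raise ValueError(f"duplicate marker id {m.marker_id!r}")
        marker_dict[m.marker_id] = m
        genomes[m.genome_accession].marker_ids.append(m.marker_id)
    return ReferenceDatabase(genomes, marker_dict, sketch_k=sketch_k,
                             sketch_s=sketch_s, kmer_k=kmer_k,
                             marker_identity=marker_identity,
                             hash_seed=hash_seed)
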