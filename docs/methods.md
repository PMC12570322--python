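# Methods

This note documents the models, parameters, and numerical choices behind
`metaguide`, and what the synthetic-data experiments do and do not show.

## Pipeline model and assumptions

The pipeline assumes short reads (hundreds of bases), a reference collection
in which sample organisms have relatives at roughly species-level similarity
or better, and per-genome annotations of the ~40 universal single-copy marker
families. Contigs are reconstructed only where reads align to a selected
guide; sequence private to the sample (absent from every guide) is never
assembled — it leaves the pipeline in the leftover-reads FASTQ.

### Reference selection

Reads are mapped to marker-cluster representatives (per-family greedy
clustering at global identity ≥ 0.99, longest sequence first, ties by
marker id). A representative's breadth propagates unchanged to every member
of its cluster; this mirrors aligning only against representatives and means
a genome can be credited through a near-identical relative's marker. A
family is *covered* when breadth **strictly exceeds** `min_breadth = 0.90`;
a genome is selected when covered families / annotated families **≥**
`min_marker_fraction = 0.75`. The denominator is the families annotated in
that genome (≤ 40), which tolerates incomplete annotations. At ~1× marker
depth the expected breadth of an 800 bp gene is ≈ 1 − e^(−1) ≈ 0.63, far
below the bar, which is why selection goes empty below about 1-fold marker
coverage — the intended behaviour for under-sequenced samples (the screen is
designed around an expected 1–3× marker depth for detectable genomes).

### ANI culling

ANI between genome sketches (canonical 21-mers, bottom-1000 MinHash, fixed
recorded hash seed 42) uses the Mash point estimate
`D = −ln(2j/(1+j))/k`, `ANI = 100(1−D)`, with ANI reported as 0 when the
sketches share nothing. At s = 1000 the estimator is well within ±0.5 ANI in
the 90–100 band, which is all the 95% species threshold requires. Clustering
is single-linkage over the ≥ 95% graph: it guarantees a partition and
matches common sketch-based dereplication practice. Cluster priority is the
exact intersection of the cluster's canonical 28-mer set (static) with the
28-mers of the currently unassigned reads (recomputed each round); the loop
ends when the best intersection is zero — a cluster sharing no 28-mer with
the reads cannot recruit anything.

### Greedy within-cluster ordering

The set-cover surrogate for "genome explaining the most unassigned reads" is
sketch containment: the fraction of the genome's 1000 sketch hashes present
among the unassigned reads' 21-mer hashes. It is recomputed after every
guided pass; ties break on accession. No winner-take-all reassignment is
performed between genomes of one cluster — read exclusivity is enforced at
consumption time instead: a read is consumed exactly when its primary
alignment overlaps a retained contig interval. Reads over discarded short
islands therefore stay available to sibling references, which maximises
pangenome capture. On a stop by criterion (iii) or (iv) the failing genome's
contigs and reads are discarded and the cluster is abandoned (no later
member is tried); stopping thresholds are strict as stated ("fails to
reach 5%", "shorter than 2,000").

### Read mapper

Seed–chain–extend with exact 15-mer seeds (stride 11 plus the final
position, ≤ 64 hits per seed), diagonal bands of width `max_gap + 16`, and
at most the two best-supported candidates aligned per read. `max_gap`
defaults to half the read length: with 250 bp reads a single 125 bp indel is
embeddable and anything longer forces a clip — this single parameter
produces the insertion-bias behaviour (breaks for insertions > 125 bp, none
at 125 bp).

Two extension paths keep the mapper fast and exact where it matters:

* **Single-diagonal candidates** (the overwhelming majority) are resolved by
  the maximum-scoring contiguous segment of the match/mismatch score vector
  (a vectorised Kadane scan). Substitution-only placements never benefit
  from gaps, so this equals the optimal local alignment on that diagonal.
* **Multi-diagonal candidates** (true indels, junction reads) run a dense
  Gotoh local alignment (numba kernel) over the banded window with scores
  match +8, mismatch −9, gap open 16, gap extend 1. Cheap gap extension is
  required so a 125 bp indel (cost 141) loses to clipping only when the
  shorter flank is small; the flip side is that in random sequence a local
  alignment with cheap gaps can drift past the true ends. Drift is caught by
  the identity gate, and the DP is then retried once with gap extension set
  to the match score, which recovers the clean clipped alignment.

Alignments are accepted when the **gap-compressed identity** (matches /
(matches + mismatches + gap events)) is ≥ 0.90 over ≥ 30 matched+mismatched
columns. Gap-compressed identity is the deliberate choice here: counting a
125 bp gap column-by-column would cap a spanning read's identity at 0.67 and
make legitimate gap-spanning impossible; compressing each contiguous gap to
one column keeps the 0.90 gate meaningful for both substitutions and
structural gaps. One primary alignment is kept per read (ties: position,
then reference order, then forward strand); mates are mapped independently.

### Coverage, breaks, and contigs

`depth[i]` counts alignments whose reference span covers *i* (deleted
columns included, so `sum(depth)` equals total reference-consuming bases);
`span_depth[i]` requires ≥ 30 aligned bases on both sides of *i* within one
alignment; `clips[i]` counts soft-clips of ≥ 20 bases ending or starting at
*i*. Contigs are maximal positive-depth runs, additionally cut at positions
with positive depth, zero spanning depth, and ≥ 2 clips within ±2 bases
(the cut lands on the position with the strongest raw clip signal — the
structural-difference signature used for guide deletions, which leave depth
continuous but unspanned). Intervals spanning < 500 reference bases are
dropped. Zero-coverage detects guide insertions (reads cannot align inside
inserted sequence); the clip/span rule detects guide deletions of length
(max_gap, ∞) — deletions up to `max_gap` are spanned as read-side insertions
and silently corrected by polishing, the known small-deletion blind spot of
guided assembly.

### Polishing

Per column: if depth ≥ `min_depth` (2) and the plurality allele (base or
deletion) differs from the reference with fraction **strictly greater** than
`min_fraction` (0.6), the edit is applied; a fraction exactly at the
threshold keeps the reference (conservative, deterministic). Insertions
after a position are applied when the modal inserted string reaches the same
fraction of reads spanning that junction and is ≤ `max_indel` (50) bases.
One polishing round is performed; on error-free fixtures it is a fixed point
(re-polishing applies zero edits). No base-quality weighting, ambiguity
codes, or local reassembly — the polisher's contract is nucleotide-level
consensus, not parity with heavier polishing tools.

### Metrics and outputs

NG(x) = largest contig length *c* such that contigs of length ≥ *c* sum to
**strictly more** than x% of the genome size; undefined (NA) when the
assembly never reaches the target. Representativeness = fraction of input
reads with an accepted primary alignment to the final contigs. AGP rows use
object coordinates on the guide (1-based inclusive, pre-polish spans) and
component coordinates on the polished contig (1..len); uncovered stretches
between retained contigs are written as U rows carrying the actual gap
length (gap_type `scaffold`, linkage `no`). The bundled validator enforces
this dialect (column count, per-object part numbering, coordinate
contiguity, U-length consistency); it does not require object span ==
component span because polishing may change contig length.

## Synthetic data: what it emulates, what it does not

`simdata` generates i.i.d. random genome backgrounds with 40 family-specific
~800 bp marker templates planted at non-overlapping positions. Each genome's
copy of a family diverges 8% from the family template, so different species'
copies sit ~15% apart — far enough that reads never cross-map between
species at the 0.90 identity gate, while strain variants (≤ 1% SNPs) of one
genome keep their markers inside the 99% clustering threshold. Reads are
250 bp pairs, fragment length N(500, 50²), positions uniform, substitution
errors i.i.d.; pair counts per genome scale with abundance × length
(default community abundances are log-spaced over one decade). Guide
perturbations plant one random-alphabet insertion or one deletion per guide
copy, ≥ 2 kb from either end. Every generator is a pure function of
(parameters, seed).

Not emulated: realistic error profiles (quality ramps, indel errors), GC or
coverage bias, repeats and mobile elements, real phylogenetic structure.
Passing tests therefore demonstrate the algorithmic contracts (selection
gates, break logic, consensus recovery, bookkeeping) — not performance on
real communities, where divergence between sample and reference, repeats,
and uneven coverage dominate. One realistic artifact the simulations *do*
surface: short conserved marker stretches can satisfy the identity gate
across species, so the first genome assembled may consume a handful of a
sibling's junction reads, occasionally adding a contig break at a marker
edge. This is inherent to guided assembly with read exclusivity and does not
measurably reduce breadth in the test communities.

## Problem sizes used by the test suite and acceptance script

The perturbation experiments use a 200 kb genome at 20× (error-free 250 bp
pairs) over the full 125–1,250 bp grid; community end-to-end tests use three
60 kb genomes at 20×; greedy-ordering oracle instances stay ≤ 8 genomes and
≤ 512 reads; polishing recovery uses a 50 kb genome with ~100 SNPs and 10
small indels at 20×. These sizes were chosen as the smallest at which every
gate of the pipeline (selection, culling, greedy ordering, breaking,
polishing, depth response) is exercised with comfortable statistical margins.

## Known limitations

* Pair information is not used for rescue or scoring; mates map
  independently.
* Only primary alignments are kept; secondary placements are discarded
  (cluster-level read exclusivity already handles redundancy).
* Deletions in the guide up to `max_gap` are spanned and corrected by
  polishing rather than reported as structural events.
* The marker-representative → member propagation credits every member with
  the representative's breadth; a genome whose markers are all ≥ 99%
  identical to a present genome's markers can be selected without
  contributing reads (the ANI culling stage then merges such genomes into
  one cluster).
* The database is held in memory; the design targets sample-scale and
  benchmark-scale collections, not a full RefSeq-sized store. Quality flags
  of public collections (e.g., "atypical"/"contaminated" annotations) are a
  curation concern outside this package: build databases from already
  filtered genomes.
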