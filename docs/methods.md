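# Methods

This note records the model implemented by `vcmap`, the conventions and
numerical choices the implementation fixes, what the synthetic data
emulates, and the known limitations.

## Index semantics

The index is a compacted de Bruijn graph over the canonical k-mers of
the reference set (canonical form = lexicographic minimum of a k-mer and
its reverse complement). Construction splits references into contigs at
any non-ACGT character; k-mers never span a split. A unitig is a maximal
non-branching path: an extension step requires the current node to have
exactly one successor and that successor exactly one predecessor, with
contig ends, branch nodes and already-placed nodes terminating the walk;
isolated cycles are swept afterwards from a deterministic entry point.
Every distinct canonical k-mer occupies exactly one (unitig, offset) —
asserted during construction — and the oriented unitig occurrences tile
each reference exactly over its non-N stretches (checkable with
`build_index(..., verify=True)`).

k must be odd (no palindromic k-mers, so strand assignment is total) and
at least 15; both guards can be overridden together with
`allow_small_k=True` for toy inputs, at the cost of admitting palindromes
whose orientation is reported as forward by convention.

All coordinates are 0-based half-open; orientation is a boolean
`forward`, rendered as `f`/`r` only in text formats. Serialization is a
versioned plain-text container holding k, the reference table, unitig
sequences and the U→R occurrence list; the K→U table is a pure function
of the unitig set and is rebuilt on load (round trips compare equal).

## Virtual colors

The scheme is fully determined by the reference lengths and two
integers: the stride `ℓ_vcol` (default 1000, the best-accuracy setting
for the mapper's defaults) and the overlap `ov_length`. The overlap must
be at least the read length for the boundary guarantee to hold (the
library warns when told otherwise) and at most `ℓ_vcol` — beyond that a
position would lie in three or more bins, which the one-or-two-id
assignment rule cannot express, so `build_scheme` rejects it. The CLI
defaults `ov_length` to twice the longest observed read (floor 150,
capped at the stride). Schemes are computed on the fly from the lengths
recorded in the index and never serialized.

Bin assignment anchors on the k-mer's *start* coordinate: position `p`
maps to bin `⌊p/ℓ_vcol⌋`, plus the next bin when
`p mod ℓ_vcol ≥ ℓ_vcol − ov_length`. The start anchor makes the overlap
test a pure modulus and is stable under canonicalization. Its one
visible consequence: with `ov_length = 0` a read is lost at τ=1 exactly
when it extends ≥ k bases past a bin boundary (at k−1 bases past, the
last k-mer still starts in the left bin). The `V+1` assignment is
suppressed at the last bin of each reference, since bins never cross
reference boundaries.

## Mapping conventions

* `|K(Q)|` counts only k-mers with an index entry, so substitution
  errors shrink the denominator rather than vetoing the read; k-mers
  containing non-ACGT characters are excluded.
* Support is tallied per (virtual color, read orientation), each read
  k-mer counted at most once per pair; orientations are never pooled
  because mate merging requires opposite orientations.
* The reported position derives from the leftmost-in-read supporting
  k-mer (ties within a bin resolved to the smallest reference
  coordinate). The inference is orientation-aware: a forward read starts
  at `anchor_pos − anchor_offset`; a reverse-complemented read's k-mer at
  read offset `i` begins `rl − k − i` bases after the read start, so the
  start is `anchor_pos + k + anchor_offset − rl`. Both clamp at 0. The
  naive "subtract the read offset" rule is only correct for forward
  hits; using it for reverse hits would shift every reverse mate and
  break exact-coordinate evaluation.
* Threshold comparison is `support ≥ τ·|K(Q)|` in double precision; the
  test oracles use the identical expression.
* Duplicate hits (equal orientation, reference and position, induced by
  the bin overlap) keep the smaller color id; groups larger than two
  violate a structural guarantee and raise `MappingInvariantError`.
* Merge bounds default to dovetail 20 / insert 1000. The fragment
  interval runs from the smaller mate start to the larger mate start
  plus that mate's read length. The best-support filter keeps all ties;
  a pair emits a fragment only when exactly one merged mapping survives
  (multimapped pairs are counted and discarded).
* Streaming query and the terminal-k-mer cache (default capacity
  5,000,000 entries, write-once: an existing entry is never replaced)
  change lookup cost only; tests assert byte-identical output across all
  four on/off combinations. A k-mer is treated as terminal when the
  previous k-mer's distance to its unitig end is smaller than the read
  offset delta (i.e. zero, for consecutive k-mers), which is exactly the
  moment traversal crosses into a new unitig.
* An optional pre-mapping mate merge (3′ overlap ≥ 20 bases, ≤ 2
  mismatches, merged sequence mapped single-end under the same threshold
  rule) exists but is off by default and excluded from acceptance; the
  parameters are this package's own choice.

## Fragment pipeline

Barcode correction accepts exact permit-list members, else a *unique*
Hamming-distance-1 neighbour; zero or multiple candidates drop the
fragment under the default policy. The opt-in `frequency` policy
resolves multi-candidate cases toward the candidate with the strictly
highest exact-match count observed in the run (count ties still drop).
Distance-1-with-uniqueness is the conservative deterministic reading of
nearest-neighbour correction; anything looser would need error-model
assumptions the data does not justify.

Sorting is by (reference appearance order in the FASTA, start, end,
barcode); with a chunk size set, sorted runs spill to temporary files
and are k-way merged, with results identical to the in-memory sort for
any chunk size ≥ 1. Deduplication collapses consecutive records equal on
(reference, start, end, barcode) into one BED line whose count includes
the fragment itself, so counts always sum to the number of corrected
fragments and reprocessing a deduplicated stream is the identity. BED
intervals are 0-based half-open; the +4/−5 transposase shift is
available behind a flag and off by default.

## Synthetic data

The generator emulates: uniform-composition genomes with one repeat
family placed at non-overlapping positions (first copy verbatim, later
copies mutated per-base at the divergence rate — so two copies differ at
about `divergence × length` sites), optional N-gaps; FR-oriented pairs
with Normal(250, 50) fragment lengths clipped to [read length, reference
length], i.i.d. substitution errors, barcodes drawn uniformly from a
generated permit list with single-base errors at a set rate, and
exact-copy fragment duplicates at a set rate. Mate 1 reads the left
fragment end on the forward strand for roughly half the pairs and the
right end reverse-complemented for the rest.

What it deliberately does not model: indels (kept out so that
tolerance-0 coordinate truth stays sharp), quality-score-dependent
errors, non-uniform base composition and the heavy-tailed repeat
landscape of real chromosomes, chimeric fragments, and
accessibility-biased fragment placement. Passing tests therefore
demonstrate the correctness of the algorithmic contracts and the
direction of the virtual-color effect, not the absolute accuracy one
would measure on a real genome.

Test and acceptance problem sizes are chosen to keep the suite quick on
one core while still exercising every code path at meaningful scale: the
oracle-equivalence sweep uses twenty 20–60 kb genomes across a 4×3
parameter grid; optimization transparency uses 50,000 pairs on a 200 kb
genome; parameter recovery uses a 1 Mb repeat-free genome with 20,000
pairs (accuracy and mapping rate ≥ 0.99 at tolerance 0); the
virtual-color direction check uses a 300 kb genome with 10% duplicated
content at 5% divergence, where accuracy is monotone non-increasing
across strides {1 kb, 100 kb, whole reference}.

## Limitations

* The index is an in-memory dictionary-based structure targeting desk
  scale (≲ 100 Mb of reference); it implements the semantics, not the
  compressed layout, of minimizer-bucketed production indexes.
* The intermediate mapped-record stream is a documented TSV (with a pair
  name column for truth joining), not a binary reduced-alignment file.
* Whole-chromosome-scale accuracy figures require a real genome and
  reads at millions-of-pairs scale and are outside what the synthetic
  generator claims to reproduce.
* Multimapped pairs are discarded rather than rescued probabilistically.
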