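# Methods

## Problem and model

A feature-barcoding experiment (ASAP-seq, CITE-seq) measures surface-marker
abundance by sequencing antibody-conjugated oligo tags together with a cell
barcode and a UMI. The counting problem is assignment, not alignment: each
read pair must be matched against two short reference lists — a whitelist of
valid cell barcodes (from the chemistry manufacturer, or the cells called by
a companion ATAC/RNA pipeline) and the antibody panel's tag table — and PCR
copies of the same original molecule must be collapsed to one count.

`adtcount` models a read pair as three fixed windows: a cell barcode
(default bases [0, 16) of the cell-ID read), a UMI (default bases [16, 28)),
and a tag (default bases [0, 16) of the oligo read). All window offsets and
lengths are configurable; reads too short for their windows are skipped and
tallied, never truncated or padded. Base qualities are ignored — error
tolerance is handled in the matching metrics — and reads are used exactly as
sequenced (an optional switch reverse-complements the whitelist for
chemistries that need it).

## Matching

Cell barcodes use Hamming distance with a default cutoff of 1 mismatch;
tags use the normalized edit similarity 1 − Levenshtein(query, ref)/|ref|,
clipped below at 0, with a default cutoff of 0.93. The two defaults agree:
one substitution in a 16-bp tag gives 1 − 1/16 = 0.9375 (passes), two give
0.875 (fails). Allowing more mismatch is known to recover few additional
reads; both cutoffs are user-adjustable.

Three deliberate choices:

* **Ratio denominator.** The reference length, not the alignment length:
  it reproduces the one-mismatch-at-16-bp equivalence above, and for pure
  substitutions on equal-length strings the alternatives coincide anyway.
* **Ambiguity.** Any sequence meeting the cutoff for ≥ 2 references is
  dropped, even when one hit is strictly better (including an exact hit
  shadowed by a neighbour at distance 1). This is conservative and
  deterministic; rescue rules would make counts depend on tie-break
  details. Ambiguous reads are reported both as read counts and as distinct
  offending sequences.
* **N bases.** `N` matches nothing, including another `N`. Internally
  query `N`s are recoded to a character outside the reference alphabet so
  both the Hamming and the edit-distance paths apply the same rule.

Batched matching splits the input into chunks (default 100,000 sequences)
processed across a thread pool. Hamming matching is a vectorized
query × reference mismatch count, blocked so the intermediate tensor stays
around 32 M elements; ratio matching memoizes per distinct tag sequence
(panel sizes are ~10²; distinct observed tags are few relative to reads).
Both paths are defined by — and tested bit-identical to — the brute-force
all-pairs scan, for every chunk size and thread count.

## UMI deduplication

The dedup key defaults to (cell, UMI); a (cell, oligo, UMI) scope is
available since many tools use it. Exact mode keeps the first occurrence of
each key in input order. Fuzzy mode builds, within each key group, a graph
on distinct UMIs with edges at Hamming distance ≤ 1 (configurable), takes
connected components, and keeps one representative per component: the most
frequent UMI, ties broken lexicographically, surviving as its first input
occurrence. Hamming is the right UMI metric here because UMIs are extracted
as fixed-width windows, and at one mismatch it coincides with edit distance.

Both modes are idempotent, preserve input order among survivors, and
satisfy n_input = n_survivors + n_removed. The per-UMI report gives each
key's (or component's) total count and duplicate fraction; the mode
comparison reports, per component, the duplicates each mode identifies and
the normalized difference — extra duplicates found by fuzzy, divided by the
component's total count — plus the fraction of components with zero change.
No directional or abundance-threshold UMI-network scheme is attempted:
connected components with a frequency representative is deterministic,
order-independent and standard.

## Pipeline

Cell and tag matching are computed independently, then combined: only reads
unique on both sides survive to dedup, and each surviving read increments
counts[oligo, cell]. The matrix always has |panel| × |whitelist| dimensions
regardless of which entries are nonzero. The run report carries every
stage's tally and a full parameter echo, and its internal ledger is checked
at run time: status partitions sum to the matched read count, and
reads_in_matrix = reads_assigned − duplicates = the matrix grand total. An
empty matrix is a valid result (exit 0); errors are reserved for malformed
inputs, and a failed run removes any partially written outputs.

Output is the CellRanger triplet — `matrix.mtx.gz` (MatrixMarket
"coordinate integer general", 1-based, column-major nonzeros),
`barcodes.tsv.gz`, `features.tsv.gz` with the literal feature type
"Antibody Capture" — plus an optional dense CSV. Gzip members are written
with a zeroed timestamp so reruns are byte-identical.

## Synthetic data

The simulator emulates the generative process the pipeline inverts:
molecules are drawn per (cell, oligo) pair from a Poisson with configurable
mean (default 5); each read can carry per-base substitution errors in its
barcode, UMI and tag windows independently; PCR re-emission duplicates a
read with the same UMI, fuzzy re-emission with a one-base-off UMI; ambient
reads carry barcodes off the whitelist; and an "ambiguity bait" option
plants a whitelist pair at Hamming distance 2 plus reads equidistant
between them, which a 1-mismatch matcher must drop. Read order is shuffled
so the pipeline can assume nothing about ordering; everything is
deterministic per seed, down to bytes.

The truth matrix counts distinct molecules for whitelist cells, so it is an
exact oracle under controlled conditions. Three generator choices make that
oracle airtight rather than merely probable:

* references are drawn with pairwise Hamming distance ≥ 3, so a one-
  substitution read is still nearer its true reference than any other;
* molecule UMIs within a cell are also drawn at pairwise distance ≥ 3, so a
  one-base duplicate twin can only connect to its own parent — without
  this, rare distance-2 UMI pairs let a twin bridge two true molecules and
  fuzzy dedup undercounts by one;
* `max_subs_per_window` optionally caps injected substitutions per window,
  realizing the "at most one substitution per barcode and per tag" regime
  exactly rather than in expectation.

What the simulator does **not** model: quality scores, fragment-length or
per-cycle error profiles, barcode-dependent amplification bias, indels
(except an off-by-default tag-indel switch for stressing the ratio metric),
and chance UMI collisions. Passing on simulated data therefore demonstrates
the pipeline's combinatorial correctness — extraction, matching, ambiguity
handling, dedup, bookkeeping — not robustness to instrument-specific noise.
On real data, component-based fuzzy dedup will occasionally merge distinct
molecules whose UMIs collide within the mismatch threshold; this is
inherent to the method class, not specific to this implementation.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: up to 200 cells × 20
oligos at mean 5 reads per pair (~25k reads), 1,000-sequence matching
batches against 8 references, and chunk sizes from 1 to 100,000 — sizes
chosen so the full suite completes in seconds while still crossing every
chunk boundary and threading path. All comparisons in the package are on
integers or exact rationals (distances, counts, ratios of small integers),
so no floating-point tolerances are needed anywhere; similarity cutoffs are
compared with ≥ on exactly representable values.

## Known limitations

* Matching is brute force against the reference lists (vectorized or
  memoized, but O(reads × references)); no k-mer index or ANN acceleration.
  Correctness is defined by the brute-force oracle; speed is best-effort.
* No cell calling: the whitelist *is* the cell set. No normalization,
  clustering or downstream statistics.
* Which physical read (R1/R2/R3) carries each component varies by platform
  and kit; the layout flags exist precisely because this cannot be guessed.
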