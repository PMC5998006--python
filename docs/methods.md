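# Methods

## Coordinate model

Chain files follow the UCSC convention exactly: 0-based half-open spans,
source strand always `+`, and strand-local coordinates on a `-` strand
destination (plus-strand position = `q_size − 1 − local`). Segment and
probe tables use 1-based inclusive coordinates, the de-facto convention
of CNV segment files; they are converted to 0-based internally and back
on output. The end of a segment is lifted as the base *at* position
`end`, not `end + 1`: endpoints are treated as points, never as
half-open boundaries, which is what makes the conversion
continuity-preserving rather than split-based. Segment length is
`end − start + 1` on both assemblies.

## Position lifting

All aligned blocks of all chains are indexed per source sequence in an
interval tree (`intervaltree`); a query position inside a block maps by
block arithmetic. Gap bases (`dt` regions) are deliberately not covered:
an unmapped answer is a first-class result, not an error. When several
chains cover one source position the highest score wins; among equal
scores the lexicographically smallest (destination name, plus-strand
position, strand) is chosen. The tie order is a package choice — what
matters is that it is total, so repeated queries, rebuilt indices and
any loading order give identical answers. Points are lifted as width-1
intervals, so no minMatch-style fractional-overlap parameter exists.

Output positions are always plus-strand destination coordinates, with
the chain strand recorded separately, because segment tables are
strandless.

## Approximate conversion

A position with no direct image is searched on the grid
`pos ± k·step_size`, `k·step_size ≤ range`, in order of increasing
distance; at equal distance the lower source coordinate wins (again: any
total order would do, this one is fixed for determinism). Negative
candidates are skipped; candidates beyond the sequence end are simply
unmapped. `range = 0` disables the search (`k = 0`, i.e. the direct
attempt, still runs). Defaults are `range = 10 000` bp and
`step_size = 100` bp: wide enough to jump typical assembly-gap scales
while bounding the positional error a rescue can introduce, and both are
CLI-overridable. The signed shift actually used is reported per
endpoint, and any nonzero shift makes the whole segment
*approximately_converted*.

## Quality control

Criteria are evaluated in the order (1) start mapped, (2) end mapped,
(3) same destination chromosome, (4) strict length-ratio bound
`1/β < old/new < β`; the reason code records the first failure only.
The ratio comparison is done by multiplication (`old < β·new` and
`new < β·old`) so the boundary cases `ratio = β` and `ratio = 1/β` are
exact in floating point and rejected, as the strict inequalities demand.
β must exceed 1; at β → ∞ criterion 4 never fires.

Two situations the criteria do not name are handled explicitly:

* **Opposite strands.** Endpoints mapped through chains of opposite
  destination strands are rejected with `strand_mismatch` — conservative,
  and logged distinctly so the cases are auditable.
* **Inverted order.** If both endpoints map (same chromosome, same
  strand) but the images come out reversed — e.g. the segment lies
  inside an inversion — the coordinates are swapped and the segment is
  *kept* when the remaining criteria pass, with `orientation_flipped`
  set in the result. Span integrity, not orientation, is the quantity
  the conversion preserves; rejecting such segments would discard
  perfectly usable spans.

Approximated endpoints feed into criteria (3)/(4) exactly like direct
ones. Probes undergo no QC: a single position has no length or pairing,
so the probe vocabulary is direct / approximate / unconvertible only.

## Batch processing

Inputs come from a directory tree or a file list; roles (segment,
probe) are assigned by filename glob, a file may hold both roles, and
work items are processed in lexicographic order. Each output is
assembled in temporary files and renamed into place *before* the
file's completion line is appended to the plain-text ledger; resuming
therefore never sees a half-written output, and a resumed run is
byte-identical to an uninterrupted one. The ledger stores the run
parameters and a SHA-256 fingerprint of the chain file; resuming under
any other settings is refused. Per-row failure details are written as a
`.log` side file next to each output, and the run-level failure log is
their concatenation in sorted order — which is what makes the global
logs reproducible across interruptions. A `--threads` option is
accepted for pipeline compatibility, but conversion is sequential;
correctness is defined per file, so any execution order would yield the
same outputs.

File-list entries are mirrored by their path relative to the list's own
directory when they lie under it, otherwise by basename.

## Synthetic fixtures and the oracle strategy

The fixture generator fabricates a rearrangement landscape — deletions
and insertions in the destination, unplaced regions that break chains,
inversions, and regions split to a new destination sequence — on source
chromosomes of a few kilobases (default 2–8 kb, ≤ 8 events; full
per-base verification of one assembly pair runs in well under a
second, so hundreds of seeded landscapes are checked per run). Events
are coordinate-only; no nucleotide sequences exist anywhere.

From one event list two artifacts are built by *disjoint code paths*:
a chain file via block/gap arithmetic, and a TruthMap that simulates
the fate of every single source base. Their agreement under the lift
engine at every base, mapped and unmapped, is the central oracle of the
test suite; the TruthMap then doubles as a brute-force reference for
segment and probe conversion (the QC rules re-applied directly to the
base map, with no chain code involved). Case files drawn from the
TruthMap carry a precomputed expected fate per row, with a fraction of
records deliberately anchored at unmapped bases so all four statuses
occur.

What the fixtures do **not** emulate: real chain files with overlapping
same-locus chains of different scores (the tie-break is tested with
hand-built chains instead), chromosome-scale sizes, duplicated
destination loci, and sequence-level effects. Passing the oracle tests
therefore demonstrates the coordinate arithmetic and the QC state
machine, not concordance with any particular external tool's
multi-chain precedence in pathological cases.

## Numerical and degenerate-input choices

* Parsing is strict: block-sum mismatches, bound violations, mergeable
  zero-gap interior blocks and truncated chains raise with the line
  number or chain id rather than being skipped.
* Duplicate chain ids are accepted (published files do not guarantee
  uniqueness); identity inside the engine is positional.
* A segment row with `start > end` is normalized by swapping before
  conversion; a width-1 segment is legal and has length 1.
* Unparseable rows are collected as per-file row errors with line
  numbers; the file keeps processing and the error count is ledgered.
* A file that fails wholesale (e.g. undecodable bytes) is marked
  `error` in the ledger; the batch continues and exits nonzero.

## Known limitations

* No BAM/SAM/BigWig conversion, no region-splitting liftover, no
  re-segmentation of probe data — all deliberately out of scope.
* Multi-chain precedence is self-consistent (score, then lexicographic)
  but not verified to be bug-compatible with any external binary.
* The approximate search is symmetric around the failed position; no
  directional (e.g. inward-only) preference is implemented.
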