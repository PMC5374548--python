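# Methods

This note documents the models and procedures pairqc implements, the
parameters that matter, the numerical choices made where the design was
open, what the simulator does and does not emulate, and known limitations.

## Overlap model

A template of length *T* sequenced from both ends at read length *S* yields
mates R1 = template[0:S] and R2 = revcomp(template)[0:S] (each padded with
adapter and then arbitrary bases when *T* < *S*). Writing C =
revcomp(R2), the mates' physical relationship is a placement of C at offset
*O* = *T* − *S* under R1: full overlap for *T* ≤ *S* (O ≤ 0), partial
overlap of length 2*S* − *T* for *S* < *T* < 2*S*, none for 2*S* ≤ *T*.

`find_overlap` searches offsets exhaustively over
[−(len(R1) − min_overlap), len(R1) − min_overlap], scoring each candidate by
the Levenshtein distance of the aligned slices (computed with edlib). The
search is globally optimal; at our read lengths (≤ a few hundred bases) the
O(offsets × alignment) cost is negligible. Ties are broken toward larger
overlap, then smaller |O|, then non-negative O — the least destructive
interpretation, since a negative offset triggers adapter cutting. A pair
counts as overlapped when the overlap length reaches `min_overlap`
(default 30 bp) and the edit distance is at most
floor(`max_ed_fraction` × overlap length) (default 5%). These two
acceptance thresholds are this package's defaults, exposed on the CLI.

**Adapter cutting.** For an accepted negative offset, *T* = *O* + len(R2);
both mates keep their first *T* bases. No adapter sequence is needed; the
cut position comes entirely from the alignment.

**Correction.** Correction requires the overlap to differ only by
substitutions, verified by Hamming distance = edit distance on the aligned
slices; indel-bearing overlaps are uncorrectable and the pair is routed to
the bad stream (reason `overlap_indel`). A mismatch is corrected when one
base has quality ≥ `qual_high` (Q30) and the other < `qual_low` (Q15): the
low-quality base and its quality are overwritten by the high-quality mate's
(complemented across strands). Q30/Q15 quantify "very high/low quality" and
are shared with error profiling.

**Error profiling.** Overlaps longer than `profile_min_overlap` (50 bp)
accumulate total bases and positional mismatches; mismatch/total estimates
the per-base error rate. Each quality-asymmetric mismatch increments one of
the 12 ordered true→observed substitution categories, with both bases
expressed in R1 orientation (a convention — the template strand of a
fragment is unknowable from the reads alone). Balanced-quality mismatches
are counted but unattributed (`unprofiled`). The estimate is slightly
biased low because pairs whose mismatch count exceeds the edit-distance
acceptance cap are excluded; at realistic error rates (≤ 1%) and 70 bp
overlaps the truncation is well under the estimate's sampling noise when
errors sit on one strand, and the profiling threshold keeps short, spuriously
aligned overlaps out.

**Merging.** The overlap region can be emitted as a single read in R1
orientation with per-position max quality. After correction the mates agree
everywhere except uncorrectable positions, where R1's call is kept.

## Global trimming

One (front, tail) cycle trim per file, applied to every read identically so
that duplicate reads remain identical (per-read trimming breaks
mapping-position de-duplication). The decision expands a good region
outward from the central cycle floor(n/2) (assumed good) and stops per side
at the first abnormal cycle. A cycle is abnormal if any of:

1. any single base's content > 40% or < 15% (N exempt);
2. any base's content changes by > 10 percentage points vs the neighbour
   cycle toward the centre;
3. GC (over A/C/G/T) > 70% or < 30%;
4. mean quality < Q20.

All comparisons are strict. The front side applies only (3) and (4):
content unflatness at the read start typically reflects the fragmentation
chemistry and is biologically real, while tail unflatness is an artefact —
so tails are trimmed aggressively and fronts conservatively. Trims are
capped at floor(10% n) front and floor(5% n) tail so chaotic profiles cannot
consume the data. Content-change direction (2) is measured toward the
centre; percentages use all bases including N in the denominator (GC
excludes N). Cycles supported by < 10% of the maximum per-cycle coverage
(sparse tails of variable-length input) are never called abnormal. Note the
arithmetic coupling at the GC boundary: with N ≈ 0, GC > 70% forces some
base below 15%, so criteria (1) and (3) often fire together; the trimming
boundary at 70% is unaffected.

## Filters

* **Quality/N**: fail if #N > 5, or more than `max_low_qual` bases
  (default 40% of the read length) fall below Q15, or mean quality < Q20.
  These numeric defaults are this package's own, chosen permissive and
  consistent with the trimmer's Q20 criterion.
* **polyX**: a read is flagged when some window of exactly *P* bases
  (default 35) contains at most *L* (default 2) bases differing from a
  single base X ∈ {A,C,G,T}, anchored on X at both ends so tolerated
  mismatches cannot dangle at the run edges; N counts as non-X. X is tried
  in A,C,G,T order and the leftmost qualifying span reported, making output
  deterministic.
* **Bubble**: reads whose flowcell coordinate lies strictly inside a
  detected bubble circle of their lane/tile fail; reads without parseable
  coordinates pass.

Failed reads keep their original name with ` fail:<reason>` appended and go
to the bad stream; for pairs, both mates go. The pass/fail partition is
order-independent; the reported reason follows the fixed order quality →
n_count → polyX → bubble.

## Bubble detection

On two-channel chemistry, air bubbles produce circular tile regions
enriched for polyG reads. Per lane/tile, from polyX read coordinates:

1. **Density filter**: 20×20 grid over the tile (width 2000 by default);
   keep hits in cells whose count exceeds `fold` (5) × the tile-mean cell
   count.
2. **Clustering**: connected components of the radius-eps neighbour graph
   (scikit-learn neighbours + scipy connected components), keeping
   components with ≥ `min_points` (20) hits. eps defaults to 1.5 grid cells
   (150): it must exceed the cell size, otherwise hits surviving in adjacent
   cells fail to connect and one bubble fragments into several clusters.
   Clusters are dropped if their enclosing-circle radius falls outside
   [tile_width/100, tile_width/4] or exceeds 3× the mean hit-to-centroid
   distance (extent dominated by outliers).
3. **Circle fit**: exact minimum enclosing circle (Welzl's
   incremental construction; the optimum is unique, hence deterministic),
   then a final radius/support filter.

Every numeric parameter here is a package default calibrated on the
simulator — none is a published value — and all are configurable. Bubble
detection is off by default; it is worth enabling for two-channel
instruments (NextSeq-class), which produce far more polyG reads. When
enabled, the input is read twice: a first pass collects polyX coordinates,
the main pass filters.

## QC diagnostics

* **Per-cycle profile**: base counts, content fractions (N in the
  denominator), mean Phred per cycle.
* **Discontinuity**: for window w (default 5 cycles), the mean over reads of
  the number of adjacent differing bases in that window (ATCGA → 4,
  AAAAA → 0). Uniform random sequence gives 4 × ¾ = 3 per 5-mer window; a
  cycle-by-cycle decline indicates per-cycle chemistry problems.
* **Strand bias**: k-mer windows (k = 8 by default, even; at most 100 000
  reads sampled) are canonicalised to the lexicographically smaller of the
  k-mer and its reverse complement and counted as forward or reverse
  accordingly. Unbiased libraries give near-equal forward/reverse counts.
  The count-weighted summary Σ|f − r| / Σ(f + r) is 0 for perfect balance
  and 1 for fully one-sided counts. Two caveats: even k admits
  reverse-complement palindromes (e.g. ACGT), which have no strand split and
  always count as forward; and sparse sampling inflates the summary (a
  singleton k-mer contributes ratio 1), so it is comparable only at similar
  sampling depth.

## Simulator

`simulate_pairs` draws templates (uniform random bases) with lengths fixed,
listed, or normal(167, 20) — the cell-free DNA regime that makes overlap
analysis worthwhile — and emits 2×`read_len` (default 100) pairs with
TruSeq-prefix adapter fill for short templates, Illumina-style coordinates,
and substitution errors planted per base at `error_rate` on both or one
mate. Qualities are two-valued (`base_qual` 36, `error_qual` 8) so the
Q30/Q15 asymmetry rule is exactly testable; planting errors at `base_qual`
exercises the uncorrectable path, `indel_fraction` the indel-discard path,
`polyx_fraction` the polyX filter, and `plant_polyx_bubble` adds a polyG
disc (default 200 hits in a radius-300 circle over ~100 background) whose
density clears the detector's 5× threshold by design. The expected
overlap-mismatch fraction (e on one mate; 2e(1−e) + ⅔e² on both) is exposed
for assertions.

The simulator does **not** emulate: quality decay along the read, indel
sequencing errors (only optional planted shifts), PCR duplicates, coverage
or GC bias, real adapter chemistry beyond a fixed prefix, or the imaging
detail of real bubbles. Tests passing on simulated data therefore validate
the algorithms' correctness against their stated models, not their
end-to-end performance on any particular instrument's artefacts.

## Numerical and degenerate-input choices

* Quality encoding is fixed Phred+33, scores 0–60; lower characters raise.
* Empty FASTQ files, empty tiles, and empty profiles are valid (zero
  outputs); empty strand-bias tables raise on summary.
* Edit distance of an empty string is the other string's length.
* Reads shorter than front + tail + 1 after trimming are routed to the bad
  stream, not raised.
* Welzl's circle uses a 1e-7 relative containment tolerance; cluster
  membership uses exact ≤ eps distances.
* Batch units are processed independently; outputs are byte-identical for
  any worker count, and per-unit failures are recorded in the summary
  rather than aborting the batch.

## Problem sizes

The test suite and acceptance script run at desk scale: 20 000 pairs for
error-rate recovery (≥ 1M overlapped bases), 2 000 pairs for correction
efficacy, 100 seeded trials each for bubble recovery and false positives,
10 000 reads for profile bounds. These sizes put sampling noise well inside
the asserted tolerances while keeping the whole suite under a minute of
compute.

## Known limitations

* Adapter detection requires overlapping pairs; single-end data gets no
  adapter handling (and no correction or error profiling).
* Correction trusts quality strings; miscalibrated qualities propagate the
  wrong base.
* The offset search assumes substitution-dominated overlaps; a true indel
  inside the overlap voids correction for that pair by design.
* Bubble detection parameters are simulator-calibrated defaults; real
  instruments may need tuning, and very large bubbles (radius > tile/4) are
  rejected by the circle filter.
* The pipeline holds one file-pair's reads in memory; files are processed
  streamingly only at the I/O layer.
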