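# Methods

## Data model and conventions

A panel is an `h × w` matrix *M* over {0,1}: one row per phased
haplotype, one column per bi-allelic site. All indices are 1-based
inclusive internally (columns `1..w`, ranks `1..h`); conversion to
0-based storage happens only at the array boundary. `PA_j` is the
permutation of rows induced by the co-lexicographic order of their
(j−1)-prefixes, with `PA_1` the identity (stable sorting of equal keys
preserves input order throughout, so the construction is deterministic).
`DA_j[i]` is the longest common suffix length of the (j−1)-prefixes at
ranks *i* and *i−1*; `DA_j[1]` is defined as 0, since the top rank has
no predecessor to compare against.

A **sentinel column** `j = w+1` (the ordering by all *w* columns) is
materialized and fully sampled — every rank is treated as a run
boundary there. This costs O(h) integers and is what lets queries at
the right edge terminate: SMEMs ending at column *w* are located in
`PA_{w+1}`, and every Φ successor search is guaranteed to find a
sampled column.

## Construction

`pbwt_core.iterate_pbwt` streams `(PA_j, DA_j, col(PBWT)_j)` for
`j = 1..w+1` with the single-pass stable split on the current PBWT
column (the standard PBWT update), tracking suffix *lengths* directly
rather than match start positions. The uncompressed module is the
package's ground truth and deliberately favours clarity over speed
(O(h·w) time and space); the index builder consumes the same stream,
compresses each column, and discards the uncompressed arrays, so peak
memory during a build is one column plus the compressed output.

Construction is validated against a second, independent route — an
explicit stable sort of reversed prefixes and direct pairwise
longest-common-suffix computation — on hundreds of random panels.

## The compressed column

Each PBWT column stores: run heads `p` (first is always 1), the
interleaved rank sample `uv` (for a zero-run, the count of ones strictly
before its head; for a one-run, the zeros), the zero total `c`, the
first-run symbol, per-run thresholds, and `PA` sampled at run
starts/ends plus `DA` at run starts. "Strictly before" is forced by the
FL formula — `FL[i][j] = u_j[i] + 1` must send the first zero to
position 1 — and is cross-checked by the identity `u + v = i − 1` at
every position. Rank at an interior position is the run's sample plus
an offset; the column is never decoded on the query path.

### Thresholds

The threshold of a run `[s..e]` is the first position of the minimum
divergence value over positions `[s .. e+1]`, clamped at *h*. The extra
position past the run end is essential, not cosmetic: on a mismatch at
rank *i* inside the run, the candidate continuations are the last row of
the previous run and the first row of the next, whose common suffixes
with row *i* are `min DA[s..i]` and `min DA[i+1..e+1]` respectively.
The first minimum over `[s..e+1]` is exactly the pivot: ranks strictly
before it jump backward, ranks at or after it jump forward. (Restricting
the minimum to `[s..e]` breaks singleton runs, which would then always
jump forward; the property suite catches this immediately.) Ties are
resolved toward the forward jump, consistent with the pivot definition.

## Matching statistics (two passes)

Forward pass state is `(i, p)`: the rank in the current column and the
panel row it carries. On a match the row survives and `i` advances by
FL; on a mismatch the threshold picks the neighbouring run, the new row
is read from the PA sample at that run's boundary, and `i` advances by
FL from the boundary position. Degenerate mismatch — the column is a
single run of the opposite symbol, so the query symbol occurs nowhere in
it — restarts matching at the top of the next column (`i = 1`,
`p = PA_{k+1}[1]`); any row choice is equivalent there because no row
matches the query at that site, which forces the length to 0 in the
second pass. When the mismatching run is the first (last) of its
column, only the forward (backward) jump exists and is taken.

The backward pass computes `len[k]` as the longest common suffix of
`P[1..k]` and row `row[k]`'s k-prefix through the compressed panel view.
When `row[k] = row[k+1]` and `len[k+1] > 0`, the previous comparison
already crossed column *k* and `len[k] = len[k+1] − 1`; otherwise the
comparison restarts. This is worst-case quadratic in *w* but exact; no
amortization is attempted because correctness, not throughput, is this
implementation's contract.

SMEM extraction scans the statistics right-to-left and reports
`(j − len[j] + 1, len[j])` whenever `j = w` or `len[j] ≥ len[j+1]`,
dropping lengths below `min_len` (default 1; zero-length statistics are
never reported).

## Φ, Φ⁻¹ and divergence recovery

FL mapping of two adjacent equal symbols keeps the pair adjacent and
ordered in the next column, so the predecessor of a value *y* in `PA_j`
is unchanged until the first column `k ≥ j` where *y* sits at a run
start — and there it is the stored sample ending the preceding run.
Φ is therefore implemented as a successor search (binary search) over
the sorted list of columns where *y* touches a run start; Φ⁻¹ mirrors
this over run ends. The iterated-FL walk is retained as a second,
independent implementation and the two are asserted extensionally equal.
Divergence recovery uses the same successor search: the sampled value
shrinks by one per column walked back, `DA_j = DA_k − (k − j)`. A value
at the top of its column has no predecessor; Φ returns none and
divergence recovery raises.

Locating an SMEM `(start, ℓ)` ending at column *k* seeds at
`A[k].row` in `PA_{k+1}`, where all sharing rows are consecutive: it
adds predecessors while the recovered divergence at the current row is
≥ ℓ, and successors while the divergence at the successor row is ≥ ℓ.
Occurrences are reported in ascending panel-row order and mapped to
haplotype ids at the report boundary.

## Panel random access and the space budget

The backward pass needs random access to *M*. Each original matrix
column is stored run-length encoded (heads + first symbol), mirroring
the PBWT columns without samples. On repetitive mosaic panels the raw
columns are themselves runny, so this stays within the run-proportional
budget; on adversarially shuffled rows it can degrade toward O(h·w),
a trade-off accepted for simplicity. The suite asserts the total stored
integer count against `32·(r + h + w)`; the constant covers the sum of
all components (mapping ≈ 2r, samples ≈ 3r, thresholds r, Φ tables
≈ 5(r+h), sentinel 2h, panel access) with ample slack — measured ratios
on the test panels are near 12.

## Serialization

A little-endian binary format: magic `MUPBWT`, version, `h`/`w`/`r`,
a JSON blob of haplotype ids, then each array length-prefixed with the
minimal byte width (1/2/4/8) covering its maximum — portability over
bit-packing. The Φ tables are derived data and are rebuilt on load
rather than stored, which keeps files smaller and the format simpler;
round-trip equality of every retained field is tested, and truncated
files, foreign magic and version mismatches are rejected without
returning a partial index.

## Synthetic data

`synth_panel` emulates the repetitiveness of cohort panels with a
founder-mosaic model: `n_founders` i.i.d. Bernoulli(0.5) haplotypes;
each output row copies one founder and switches to a uniformly chosen
founder with probability `switch_rate` per site (a memoryless stand-in
for recombination), then every allele flips with probability `mut_rate`.
Defaults `n_founders=4`, `switch_rate=0.02`, `mut_rate=0.01` give a few
runs per column at test sizes — qualitatively the regime real panels
occupy (the compression argument only needs r ≪ h·w, not any particular
value). `synth_query` splits the site range into contiguous blocks
copied from random rows, guaranteeing long shared substrings so SMEM
queries exercise non-trivial paths.

What the generator does **not** emulate: linkage-disequilibrium decay,
allele-frequency spectra, population structure, genotyping error modes,
or the extreme sparsity (rare variants) of sequencing panels. Passing
tests therefore demonstrate algorithmic correctness on repetitive binary
panels, not calibrated performance on any particular dataset. Exactness,
however, is data-independent: every query path is asserted equal — not
approximately, exactly — to brute-force oracles over hundreds of seeded
random instances, including degenerate shapes (single row, single
column, constant columns).

## Problem sizes

The randomized suites use panels up to 50×60 with ≥200 seeds for the
oracle-equivalence sweep and exhaustive (column, value) coverage for
Φ/Φ⁻¹/divergence checks; these sizes fully exercise every code path
(multi-run and single-run columns, boundary runs, sentinel queries)
while keeping the whole suite fast enough to run on every change.

## Known limitations

* Build time is O(h·w): no O(h + r) per-column construction tricks.
* No dynamic updates (insertion/deletion of haplotypes), no L-long
  match enumeration, no within-panel all-vs-all matching.
* Queries must have exactly the panel's width; no padding or projection.
* Missing genotypes are rejected, not imputed; multi-allelic records
  are skipped on input.
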