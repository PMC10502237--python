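# mupbwt

Run-length compressed indexing of the positional Burrows–Wheeler transform
(PBWT) for phased, bi-allelic haplotype panels, with set-maximal exact
match (SMEM) queries: both **finding** the maximal matches between an
external haplotype and the panel, and **locating** every panel haplotype
that shares each match.

## The problem

Modern cohort panels (biobank-scale VCFs) hold *h* phased haplotypes over
*w* bi-allelic sites — an `h × w` binary matrix *M*. The classic PBWT
answers SMEM queries in linear time but keeps Θ(h·w) integers in memory:
prohibitive at biobank scale. Cohort panels are, however, extremely
repetitive: at each column *j*, sorting rows by the co-lexicographic
order of their (j−1)-prefixes (the prefix array `PA_j`) groups similar
haplotypes, so the permuted column `col(PBWT)_j = col(M)_j[PA_j]` breaks
into few maximal runs. With `r = Σ_j r_j` the total run count, this
package stores **O(r + h + w)** integers instead of Θ(h·w) — the r-index
idea transplanted from the BWT to the PBWT.

Per column the index keeps only:

* the run heads `p_j`, an interleaved zero/one rank sample `uv_j` per
  run, the zero total `c[j]` and the first-run symbol — enough to
  evaluate the forward (FL) mapping
  `FL[i][j] = u_j[i]+1` if the symbol is 0, else `v_j[i]+c[j]+1`;
* the prefix array sampled at every run start and end, and the
  divergence array `DA_j` (longest common suffix length between
  co-lexicographically adjacent prefixes) sampled at run starts;
* one *threshold* per run: the first position of the minimum divergence
  value, which decides, on a query mismatch, whether the better match
  continues from the run above or the run below.

A query haplotype `P[1..w]` is processed in two passes that compute its
**matching statistics** — per column *j*, the length `A[j].len` of the
longest suffix of `P[1..j]` shared with any row's j-prefix, and a row
`A[j].row` attaining it. SMEMs are read off in one right-to-left scan:
position *j* ends an SMEM iff `j = w` or `A[j].len ≥ A[j+1].len`.
Locating walks the **Φ / Φ⁻¹** functions (predecessor / successor in the
prefix array, answered from the run-boundary samples by successor search
over columns) outward from the matched row while the recovered
divergence stays at least the match length — the sharing rows are always
one contiguous block of `PA_{k+1}`.

## Worked example

An 8×14 panel simulated from two founder haplotypes, and a query that
copies one founder on the left half and the other on the right (plus two
mutations):

```sh
$ mupbwt build --plain demo_panel.txt --out demo.idx
INFO mupbwt: built index: h=8 w=14 r=25 (1.79 runs/column) in 0.00s

$ cat demo_query.txt
11110001111000

$ mupbwt query --index demo.idx --plain demo_query.txt --out demo.tsv --locate
$ cat demo.tsv
query_id  start_column  end_column  length  occurrences
Q1        1             7           7       H2,H5,H6
Q1        7             14          8       H1,H4,H7,H8
```

The query shares sites 1–7 with haplotypes H2/H5/H6 (the first founder
lineage) and sites 7–14 with H1/H4/H7/H8 (the second); neither match can
be extended in either direction and still occur in the panel — that is
exactly the SMEM condition. `mupbwt stats --index demo.idx` prints the
stored-integer budget per component (mapping, PA/DA samples, thresholds,
sentinel column, panel access, Φ tables); for this panel the whole index
is 407 integers against 8·14 = 112 matrix cells, and the ratio improves
rapidly with panel size since only runs are stored.

A randomized end-to-end health check of a build is available as
`mupbwt selfcheck [--h N --w N --reps N --seed N]`.

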