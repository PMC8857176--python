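# Methods

## Annotation model

A read `r` is explained against a mature arm `(precursor p, canonical
interval [s, e))` by a decomposition

```
r = p[s - d5 : e + d3]  (with ≤ max_sub internal substitutions)  +  tail
```

with 5' offset `d5` and templated 3' offset `d3` in `[-max_trim, max_trim]`
(positive = extension), a non-templated tail of length ≤ `max_add`, and
substitutions only at read positions `1 .. len-2` (terminal bases are end
variation by definition, not substitutions). Defaults `max_sub=1`,
`max_trim=3`, `max_add=3`. Two structural rules close the model:

* **Maximal templating.** A tail never starts with the precursor base
  immediately following the templated segment; such a base is always
  consumed as templated. Without this rule every templated extension would
  also admit a spurious tail decomposition.
* **Scoring order.** Among valid decompositions the winner minimizes
  `(n_substitutions, tail length, |d5| + |d3|, |d5|)`, then the
  lexicographically smallest `(precursor, mature)` and smallest `(d5, d3)`
  for full determinism. The order prefers the most templated, most
  parsimonious explanation. Ties in the first four components across
  *different* precursors keep the lexicographically first assignment and set
  an `ambiguous` flag; counts are never split fractionally.

Category membership follows directly from the fields (`CANONICAL` iff all
deviations are zero; the other four flags are independent, so one read can
contribute to several categories). The batch annotator is a vectorized
re-implementation of the scalar search and is tested for exact agreement
with it and with an exhaustive brute-force enumeration.

A known identifiability limit of the tolerance model itself: a substitution
within `max_add` nt of the 3' end has an alternative zero-substitution
decomposition as 3' trimming plus a non-templated tail, which the scoring
order (substitutions first) prefers. Any annotator with these tolerances
shares this ambiguity; the simulator therefore does not plant substitutions
there (below).

## Preprocessing

Stage order is fixed — UMI extraction (5' prefix), 3' adapter trimming,
minimum-length filter (default 15 nt) — and the API rejects reordering.
Adapter matching is substitution-only: every 3'-anchored alignment of the
read against an adapter prefix is scored `matches − errors` and accepted at
`errors ≤ floor(0.1 × aligned length)` with minimum overlap 1; best score
wins, ties to the longest then leftmost match. With minimum overlap 1 a
single terminal base equal to the adapter's first base is clipped; that is
the documented consequence of the chosen defaults, not a bug. UMI geometry
is configuration-driven (default 8 nt 5' prefix) since small RNA protocols
differ; trimming allows no indels by default for the same reason.

Deduplication groups annotated reads by `(cell, precursor, alignment start)`
— the precursor alignment supplies the positional key that a genome
alignment would otherwise provide — and collapses UMIs per group.
Default is exact-match collapse; an optional `directional` mode merges UMIs
at Hamming distance 1 when the larger count ≥ 2 × smaller − 1, the de-facto
standard adjacency rule. The representative read per cluster is the most
frequent sequence (ties lexicographic), for determinism.

## Quantification and profiles

Counting levels: parent miRNA; exact isomiR (feature identity =
`(mature, d5, d3, tail, substitution)`); miRNA × category, where a read
increments each category feature it belongs to but its parent `|TOTAL`
feature once. Cells need ≥ 1000 miRNA-mapped reads *before* deduplication to
be analyzed (the threshold is inclusive). Positional profiles report the
proportion mass at each offset in ±3 and the share of reads with ≥ 1
non-templated A (or U); per-cell proportions are computed first and averaged
unweighted across cells, so deep cells do not dominate — a pooled-read
variant exists behind a flag. Per-miRNA profiles require ≥ 50 pooled reads
by default (configurable), a floor chosen to keep per-cell proportions
meaningful at single-cell depths. Clustering uses Spearman correlation on
per-cell CPM (rank-based, so the depth normalization choice is immaterial)
and average-linkage hierarchical clustering on 1 − ρ; constant cells get
correlation 0 with a warning. An isomiR-level "relative abundance" mode
(each isomiR over its parent miRNA's per-cell reads) is provided alongside
cell-level CPM.

## Target-correlation procedure

Targets are aggregated per miRNA with the minimum-rank method over named
prediction sources, keeping genes with ≥ 2 distinct sources; the score
orders but never cuts. Category expression is CPM over the cell's
miRNA-mapped reads by default (a parent-relative mode is available); mRNA is
log1p(CPM)-transformed before Pearson correlation (defaults chosen as the
most common practice; both are parameters, and tests confirm the KS
conclusions are insensitive to raw-CPM vs log CPM on synthetic data).
Zero-variance genes are excluded as undefined. The two-sample KS test uses
the asymptotic p-value (both sides have hundreds to thousands of genes in
every intended use); direction is assigned at p < α by the sign of the
target-vs-non-target median difference — a robust, testable reading of the
shift. No multiple-testing correction modifies the per-test α; a
Benjamini–Hochberg column is emitted for reference only. Screened miRNAs are
the top expressed ones whose non-canonical read share is ≥ 10% (an
all-canonical miRNA has no isomiR contrast to test); categories other than
TOTAL/CANONICAL additionally need ≥ 10 pooled reads.

## Synthetic data: what it emulates, and what not

The generator reproduces the statistical structure the analysis relies on:
per-cell miRNA-mapped depths of 10³–10⁴, a rank-skewed abundance vector
dominated by a few species, a five-way isomiR mixture with per-category
sub-distributions (5' offsets over −3..−1 — 5' extensions are left to the
tolerance model but not simulated, matching their near-absence in real
libraries; 3' offsets over ±3 excluding 0; A/U tails of length 1–3;
uniformly placed internal substitutions), 5'-prefix UMIs, shifted-Poisson
(`1 + Poisson(mean − 1)`) PCR copy numbers with an optional
canonical-biased mean, and a verbatim 3' adapter. The coupled mRNA matrix
plants a chosen population Pearson correlation between each regulated
miRNA's per-cell molecule count and its target genes' latent log-expression
(`z = r·x̂ + √(1−r²)·ε`, emitted as lognormal expression), with a
≥ 2-source target table plus single-source decoys.

Two deliberate identifiability constraints keep ground truth recoverable:
the first tail base is redrawn if it equals the next templated base
(otherwise it *is* templated under the model), and substitutions are placed
at read positions `1 .. len−4`, i.e. also outside the 3' window where a
substitution is indistinguishable from trimming-plus-tail (see above).

Not emulated: ligation bias, sequencing errors beyond the planted
substitutions, barcoded single-FASTQ layouts, and real secondary-structure
or sequence composition of precursors (sequences are uniform random, which
makes cross-arm ambiguity much rarer than in a real miRBase reference —
passing tests demonstrate algorithmic correctness, not real-data mapping
rates). CPM normalization of the mRNA matrix introduces a small
compositional coupling (planted blocks shift per-cell totals), visible as a
slight common shift of non-target correlations; it affects targets and
non-targets alike and leaves the KS calibration at the nominal rate.

## Numerical and design choices

* All randomness flows from one seed through CRC32-keyed named substreams
  per stage/cell, so adding a stage never perturbs another's draws; outputs
  and manifests are byte-identical across reruns of the same config.
* Probability vectors must sum to 1 within 1e−9; alignment bounds ≥ 0;
  shifted-Poisson keeps copy numbers ≥ 1.
* Problem sizes in tests and in `scripts/acceptance.py` (e.g. 50 cells ×
  10⁴ reads for mixture recovery, 30 cells × 2000 genes × several hundred
  replicates for KS calibration) were chosen as the smallest sizes at which
  the binomial 3-SD bands and rate intervals are informative.
* Degenerate inputs: empty references and < 3 shared cells are errors;
  reads containing N never align; constant expression vectors yield
  undefined (excluded) correlations; an all-filtered cell set returns an
  empty matrix with a warning.

## Known limitations

Single-arm assignment (no fractional multi-mapping), substitution-only
adapter matching, no quality trimming, no genome-level alignment stage, and
the synthetic reference's lack of homologous miRNA families mean ambiguity
handling is exercised only by constructed duplicates. The directional UMI
mode is quadratic per alignment group and intended for the small group sizes
that arise here.
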