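# Methods

This note records the model, its parameters, the numerical and design
choices that were genuinely open, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Region model

A sequence of length `L` is partitioned into `n1, n2, n3, n4` (each
`d_N` residues), `M`, and `C` (`d_C` residues), in that order, as
half-open 0-based intervals. When `L >= 4*d_N + d_C` the layout is
literal and `M` takes the remainder (possibly empty). For shorter
sequences the termini shrink while preserving the nominal N:C
proportions: the N block receives `floor(L*4*d_N/(4*d_N+d_C+1))`
residues, split as evenly as possible over `n1..n4` with earlier
sub-regions taking the remainder; `C` receives
`floor(L*d_C/(4*d_N+d_C+1))`; `M` the rest. Because the floor formula
alone can starve a region for extreme `(d_N, d_C)` (e.g. `L=6, d_N=2,
d_C=8` would give an N block of 2), a deterministic repair step raises
the N block to ≥ 4 and `C` to ≥ 1 and takes the deficit from `M`, then
`C`. Every region is therefore non-empty whenever `L >= 6`; sequences
shorter than 6 are rejected. This shrink rule is this package's own
deterministic choice; any fixed alternative with the same cover/order
invariants would serve.

## Compositional features (184)

Composition over the six regions plus the full sequence (7 x 20), twin
(adjacent-identical) residue composition in `M` (20), and six-bin
distance frequencies: basic residues (R, K, H) over the concatenated N
block and over `M`, hydrophobic residues (I, V, L, F, M, A, G, W, P)
over `M`, remaining residues (D, N, E, Q, Y, S, T, C) over `M`.
Decisions:

* Distance bins hold **raw counts**, pinned by the reference example
  (`ARMRAASKAALLMAHKNAK` → gaps 2, 4, 7, 1, 3 → (1, 3, 1, 0, 0, 0));
  their sum is always `max(0, #class members − 1)` within a span.
* Basic-residue distances in the N terminus are computed on the
  concatenation `n1+n2+n3+n4`; gaps never span the N/M boundary.
* Twin counts are overlapping (`AAA` counts 2) and normalized by
  `len − 1`, making them a composition-like fraction; whether the
  original formulation normalized here is not pinned by any example, so
  this convention is fixed and test-pinned.
* Empty regions encode as zero vectors rather than errors, so very
  short peptides remain encodable.

## Physicochemical features

**Correlation pruning.** Property scales (20 values each, AAIndex1
format; scales with `NA` values are dropped at parse time) are grouped
by connected components of the graph with an edge wherever
|Pearson r| ≥ 0.9 across the 20 residue values. Absolute correlation is
used because an anticorrelated scale is equally redundant. One
representative per component is drawn uniformly under a fixed seed.
Components are computed once per table + seed. A zero-variance scale
has no defined correlation and is kept as a singleton with a warning.

**Restrictive mining.** For each (property, region): hold out each
family peptide in turn; it passes if every residue it has in that
region carries a value inside the [min, max] envelope of the region's
residues pooled over the other peptides. A peptide whose region is
empty passes vacuously; if all *other* peptides have the region empty,
the held-out peptide fails (envelope undefined); a region empty in
every peptide skips the pair. Pairs with pass fraction ≥ 0.9
(inclusive, "at least 90%") are retained. The test operates on the
region-partitioned raw sequences; a progressive-MSA preprocessing mode
(`msa` module) is provided for users who want alignment-consistent
envelopes, but the default pipeline is region-based because the region
definitions are stated on unaligned sequences.

**Median features.** Each retained (property, region) pair contributes
the median property value of the peptide's residues in that region,
computed identically for family and non-family peptides; even-count
medians average the two central values; empty regions score 0.

The `all` mode skips mining and emits every (property, region) median —
with 294 properties that is 184 + 294 × 6 = 1948 features — which is
the no-mining baseline; `basic` stops at 184.

## Alignment (optional preprocessing)

Progressive MSA: affine-gap Needleman–Wunsch (Gotoh) pairwise scores
with BLOSUM62, gap open −10, gap extend −1 (a gap of length *g* costs
`open + (g−1)*extend`), deterministic traceback preferring diagonal,
then a gap in the second sequence, then the first; a UPGMA guide tree
on `d = s_max − s` distances; profile–profile merges with sum-of-pairs
column scores (gap–residue scores the extend penalty, gap–gap zero).
Aligner parameters are configurable; a pre-computed aligned FASTA can
be loaded instead.

## Preprocessing

Constant features (a single distinct value over all peptides) are
removed first, then each feature is z-scored with mean and standard
deviation over **all** peptides (target and non-target). The sample
convention (ddof = 1) is the default — the normalization formula does
not itself fix the convention — and ddof = 0 is available.

## Clustering and evaluation

*k*-means (Lloyd, squared-Euclidean assignment, assignment-stability
stopping, max 300 iterations) starts from class-informed centroids: the
target-class mean, plus the non-target mean at K = 2. For K > 2 the
non-target rows are pre-split by a seeded k-means++ draw of K−1 centers
and their group means used — the K > 2 start was an open choice; this
one keeps the class-informed, seed-reproducible intent. An emptied
cluster is reseeded to the point farthest from its own centroid.

The cluster holding the most target peptides is the target cluster
(ties → lowest index). From the resulting confusion counts: accuracy,
sensitivity, specificity, precision, F = 2TP/(2TP+FN+FP), Jaccard =
TP/(TP+FP+FN); plus the external criteria entropy (cluster-size-weighted
class entropy, log base 2) and purity (fraction of peptides in their
cluster's dominant class). The two classical forms of F (harmonic mean
of precision/recall vs the count form) are identical whenever
precision + recall > 0, which the suite verifies.

## GA feature selection

Binary chromosomes over the candidate features; fitness
`1 − F + m/N` (an all-zero chromosome scores 2.0 without clustering).
Generational GA: tournament selection of size 2, uniform crossover at
rate 0.8, independent per-bit mutation at rate 0.01, elitism 1, initial
bits Bernoulli(0.5). The selection/crossover/elitism operators were not
externally fixed; these are standard robust defaults for binary
encodings and all are configurable. Defaults are population 1000 and
1000 generations; the examples and tests run a scaled configuration
(population 60, 50 generations) that already recovers planted optima on
desk-size problems. K is an outer loop (one GA run per K), and the
(d_N, d_C) grid — {10, 12, 14, 16} × {8, 10} — rebuilds the feature
space per cell. Grid ties break toward fewer selected features, then
smaller K, d_N, d_C. All randomness flows from a single seeded
generator; identical config + seed is bit-reproducible. Fitness values
are memoized per chromosome within a run.

## Synthetic data

The generator emulates a labelled peptide collection: families of
10–50 short peptides plus an unbiased background pool, lengths uniform
on a configured range (default 10–212, the span of mature AMPs),
residues uniform over the 20 canonical amino acids unless configured
otherwise. Signals are planted per family and region: compositional
enrichments multiply a residue's sampling weight; property restrictions
zero out residues whose scale value falls outside an interval. Ground
truth lists the corresponding feature columns.

What it does **not** emulate: phylogenetic correlation within families,
position-specific motifs, realistic residue frequencies, length/family
confounds, or secondary structure. Passing recovery tests therefore
shows the pipeline recovers signals of the planted *kind* at the tested
strength, not that real families behave like this generator.

**Recovery test conditions** (fixed once, by design): 3 families × 20
peptides + 40 background, lengths 30–60, `d_N = d_C = 10`. The target
family carries three enrichments (D in `n2`, S in `n4`, T in `C`) at
weight 8 — chosen so that a single planted feature clusters the family
only partially (F ≈ 0.8) while the three together cluster it cleanly
(F ≳ 0.93). The enriched residues are deliberately outside the basic
class and outside `M`, so no distance or twin feature correlates with
the signal and recovery is attributable to the planted composition
columns. The mining-recovery condition plants one property restriction
in `M` (8 of 20 residues allowed) in a 20-peptide family. Test scale
(population 60, 50 generations, K = 2, 10 generator seeds) is the
package's desk-scale choice; the full-scale defaults remain available.

## Numerical choices and degenerate inputs

* Peptides with non-canonical letters (B, Z, J, X, U, O, …) are skipped
  whole on input — per-residue masking would corrupt region lengths.
* Feature-matrix TSV serializes floats via `repr`, so write→read is an
  exact round trip.
* Median of an even count = mean of the two central values.
* Evaluation tie-breaks (equal target counts across clusters) go to the
  lower cluster index; k-means assignment ties resolve to the lower
  centroid index via `argmin`.
* Families need ≥ 3 peptides for mining and > 10 (configurable) for the
  full selection protocol.

## Limitations

* The GA wraps an unsupervised objective but uses labels in the
  F-measure, so selected features are descriptive of the labelled
  dataset, not a validated classifier; with many candidate features and
  few peptides the search can overfit cluster structure.
* The restrictive-envelope test becomes permissive when a family's
  region usage is diverse (the envelope then spans most of a scale's
  range); it is most informative for conserved regions.
* Exhaustive-oracle guarantees are only verified at small n (≤ 8 points
  for k-means, ≤ 12 candidate features for the GA).
* The progressive aligner is a baseline implementation (no iterative
  refinement); for publication-grade alignments use the external
  aligned-FASTA escape hatch.
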