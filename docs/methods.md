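# Methods

This note documents the models, conventions and numerical choices behind
`clustgrid`, in the order the pipeline applies them.

## Input model

The unit of analysis is an expression matrix: unique gene (probe) IDs by
sample IDs, real intensities, possibly negative depending on upstream
normalization.  Genes are the clustered items; samples are coordinates.
Missing cells are a hard load error — the pipeline performs no imputation,
because none is defensible without knowing the upstream platform.  The
on-disk form is delimited text (tab by default, comma via flag) with a
header row of sample IDs and a first column of gene IDs.  Vendor binary
formats (CEL etc.) and intensity normalization are out of scope.

## Distances and PCA

Three metrics are supported — Euclidean, Manhattan (city-block) and maximum
(Chebyshev) — computed between gene rows over all sample columns
(`scipy.spatial.distance.pdist` underneath).  Entrywise they satisfy
maximum ≤ Euclidean ≤ Manhattan; all three are proper metrics.

PCA is available as an optional preprocessing step and is **off by default**:
the core grid is defined on raw intensities, and applying Manhattan or
maximum distances in a rotated basis changes their meaning (neither is
rotation-invariant), so the default keeps each metric's geometry literal.
When enabled, columns are centered but not scaled — unit-variance scaling
would erase exactly the column-variance heterogeneity that differentiates
the metrics — and the smallest number of leading components reaching the
requested cumulative explained-variance fraction is kept (components with
numerically zero singular value, below 1e−12 of the largest, are always
dropped).

## Agglomeration

All four linkages run on one from-scratch agglomerator using Lance–Williams
updates (single: min; complete: max; average: size-weighted mean; Ward:
variance-increase form).  Conventions:

- **Tie rule.**  Among pairs at the minimal dissimilarity, the pair whose
  (smaller node id, larger node id) is lexicographically least merges first.
  Leaves are 0 … n−1, internal nodes n … 2n−2 in merge order.  The
  brute-force test oracle applies the same rule, making trees fully
  deterministic.
- **Ward scale.**  Ward heights are reported on the variance-increase
  (Lance–Williams) scale without square-rooting.  Only the relative order of
  heights matters to the cut scan, and the un-rooted scale round-trips
  exactly through the recurrence.
- **Ward on non-Euclidean input.**  The Ward update is applied verbatim to
  whatever dissimilarity matrix is supplied, Manhattan and maximum included,
  so the full 12-cell grid is well defined.  Caveat: Ward's
  variance-minimization interpretation assumes squared-Euclidean geometry;
  on other inputs it is simply the corresponding Lance–Williams objective.
- All four linkages are monotone, so merge heights never decrease; cutting
  at a height and cutting into k clusters are interconvertible, and cluster
  labels are canonical (numbered by smallest member index).

The agglomerator is exact O(n³)-worst-case (vectorized per step); no
nearest-neighbor-chain acceleration is used.  At the study sizes (hundreds
to a few thousand genes) this is seconds.

## Fitness and the cut-point scan

A partition is scored by average silhouette width S and mean within-cluster
centroid distance W.  Silhouette uses the standard a/b construction on the
pairwise distance matrix; items in singleton clusters score 0 by convention
(as in scikit-learn, which serves as a cross-check oracle in the tests), and
s(i) = 0 whenever max(a, b) = 0 (identical points).  W uses arithmetic-mean
centroids for every metric — a coordinate-median centroid would be the
L1-optimal choice for Manhattan but the plain centroid definition is kept
for all cells — and aggregates as the item-weighted mean over all genes, so
singletons contribute 0 without destabilizing the average.  W is always
measured in the same metric as the cell under evaluation, keeping each grid
cell internally one geometry.

The combined fitness is **F = S / max(W, ε)** with ε = 1e−12.  The exact
algebraic combination is the one genuinely open design point in this
pipeline: F must increase with S and decrease with W, and the simple ratio
is the minimal such form; it also naturally produces very small magnitudes
on raw-intensity data where W is large.  The choice is isolated behind
`fitness_score` so an alternative (product, weighted sum) can be swapped in
one place.  Degenerate input (all rows identical) yields S = 0, W = 0,
F = 0 rather than an error.

The scan enumerates cluster counts k = 2 … min(n−1, k_max) (default cap
300), visiting every distinct partition of the dendrogram exactly once —
scanning heights would visit the same set.  Ties in F break toward smaller
k (parsimony).  The scan requires n ≥ 4 so at least one admissible k
exists.  Internally the scan peels merges from the root, so all cuts
together cost O(n²) plus one silhouette evaluation per cut.

## Consensus clustering

All three consensus methods consume base partitions over the same items and
a fixed target k, conventionally the cluster count of the best grid cell
(the 12 grid partitions are the default base set — the comparison protocol
is otherwise under-determined, and using all cells exercises the full grid).

- **CSPA**: the co-association matrix (fraction of base clusterings placing
  a pair together) is converted to a dissimilarity (1 − entries) and
  clustered with the package's own average-linkage agglomerator, cut into
  k.  The partitioner is a parameter; average linkage is the default.
- **HGPA**: items are vertices, every base cluster a hyperedge; a k-way
  partition approximately minimizing cut hyperedges is found by recursive
  bisection.  Each bisection orders items spectrally (Fiedler vector of the
  star-expansion graph Laplacian; disconnected inputs are ordered
  component-block-wise) and then picks the admissible split point with the
  fewest cut hyperedges.  Ties prefer splits leaving each side at least as
  many hypergraph components as the clusters it must still produce — this
  guarantees that a zero-cut k-way partition, when one exists (e.g.
  identical base clusterings), survives the recursion — then proportional
  balance.  This is an approximation of the hypergraph-min-cut family; on
  small instances the tests verify it attains the exhaustively enumerated
  minimum cut.
- **MCLA**: base clusters become meta-objects under Jaccard dissimilarity
  of their membership indicators, grouped into k metaclusters by average
  linkage; items join the metacluster with the highest mean membership
  (ties toward the lower label).  A metacluster that wins no items triggers
  an explicit warning and a compactly relabelled output.

Idempotence (identical bases in, same partition out, up to label
permutation, when target k matches) holds for all three methods and is
checked via maximum-agreement bipartite label matching.

## Pleiotropy stage

Disease datasets generally have unequal sample counts, so a shared gene's
rows cannot be stacked into one matrix.  Each gene is instead summarized per
dataset by mean, median, SD and variance (sample, n−1 denominator — the
columns are patient samples), giving a diseases × 4 secondary matrix per
gene.  Gene matching is exact string equality of IDs; no fuzzy or alias
resolution.  The four summary columns are used unstandardized by default
(all are on the expression scale); because variance is on a squared scale
and can dominate, a z-score option standardizes the columns.  The per-gene
disease tree uses the grid's best combination by default (maximum-average
in the packaged drivers).

## Synthetic data

The generator emulates the benchmarked collection's shapes — medium
(~2,000–7,000 genes × 60–80 samples) and large (~12,000–15,000 × 180–250)
regimes, run at 10×-reduced sizes (200 × 60 and up) in the tests and
drivers to keep runs in seconds-to-minutes.  Structure:

- **Centers.**  k cluster centers on scaled standard-basis vectors (a
  regular simplex), so all pairwise center distances are equal and
  `separation` is a single knob.  This placement requires k ≤ n_samples
  (trivially satisfied at study shapes).
- **Separation units.**  `separation` is the center distance in units of
  the RMS distance between two same-cluster genes, noise_sd·√(2p).  In p
  dimensions that — not the per-coordinate SD — is the scale on which
  Gaussian clouds overlap: defined per-coordinate, a nominally "large"
  separation of 10 is smaller than the ~√(2·60) ≈ 11 within-cluster pair
  distance at p = 60 and the clusters merge under the Manhattan metric.
  With RMS units, separation 1 means clusters about as far apart as they
  are wide, and separation 10 means essentially disjoint clouds under all
  three metrics — the regime the recovery tests assume.
- **Noise.**  i.i.d. Gaussian per cell.  The heteroscedastic profile
  multiplies each column's SD by a log-uniform draw from [0.2, 5],
  recreating the non-uniform per-column variance under which the maximum
  metric distinguishes itself.  Near-equal contiguous label blocks keep
  every planted cluster non-empty.
- **Collections.**  Multi-dataset collections plant exactly
  `shared_gene_count` gene IDs in every dataset (all other IDs
  dataset-unique) with dataset-specific means for the shared genes, drawn
  N(0, 2) by default or supplied explicitly, so summary statistics
  genuinely differ across datasets.
- **Determinism.**  All draws come from `numpy.random.default_rng(seed)`
  (PCG64), fixed across platforms; identical specs give bit-identical
  matrices.

What the generator does **not** model: probe-level microarray physics,
gene–gene correlation structure, batch effects, or heavy-tailed noise.
Passing recovery tests therefore demonstrates that the pipeline's machinery
is correct and that its statistics behave as designed on well-specified
Gaussian structure — not that any particular metric-linkage combination is
superior on real tumor data.

## Problem sizes and tolerances

Test and driver sizes: oracle equivalence on ≥100 random matrices (n ≤ 15
for linkage, n ≤ 30 for silhouette); recovery on 200 × 60 matrices over 20
seeds; the full default test suite and the acceptance script each run in a
couple of minutes on one CPU.  Numerical tolerances: linkage heights match
the recompute-from-scratch oracle within 1e−9 (observed ~1e−14); silhouette
matches brute force within 1e−12 (float-roundoff equality; the vectorized
kernel sums in BLAS order); Newick branch lengths serialize with shortest
exact round-trip formatting so re-parsed leaf-to-root depths reproduce merge
heights to accumulation error.

## Known limitations

- The F = S/W form is an inference from the constraint "increasing in S,
  decreasing in W" (see above); other monotone combinations would rank cuts
  differently in principle.
- HGPA is a heuristic approximation; optimality is only verified on small
  instances.
- Ward on non-Euclidean dissimilarities has no variance interpretation.
- Whether to apply PCA before non-rotation-invariant metrics is left to the
  user and defaults to off.
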