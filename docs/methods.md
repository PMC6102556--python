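# Methods

This note documents the models, conventions, parameters and numerical
choices behind `phylogrid`, and what the synthetic-data experiments do
and do not establish about real data.

## Grid aggregation

Occurrence records (taxon, x, y) are assumed planar equal-area in
meters; the package performs no reprojection. Cells are half-open
squares `[low, high)` of side `cell_size` (default 25 000 m) assigned
by floor division, so a point exactly on an edge belongs
deterministically to the higher cell. The grid origin defaults to the
floor of the data minimum to the nearest cell multiple and is
configurable, since real analyses rarely state one. Cells without
records are never materialized: absence is encoded as a missing cell,
not a zero, which keeps the cross-taxon concordance semantics clean
("unsampled" is not "zero diversity"). The optional domain mask keeps
points on the polygon boundary (shapely `covers`), a choice that
matters only for records exactly on the study-region outline.
Taxonomic name handling is exact string matching plus the
`align_matrix_to_tree` policies (`strict` errors on mismatch;
`prune-both` intersects and prunes); synonymy resolution is out of
scope.

## Branch accounting

"Counted branches" are every branch except the stem above the root
node. A stem above the root is arbitrary, and Faith-style PD
conventionally spans tips to the root, so the stem is excluded from
totals, from equalization and from every metric (it is retained on the
tree object). PD and PE use the tips-to-root path convention by
default; a crown (spanning-subtree) variant is available via
`convention="crown"`, under which branches ancestral to all of a
cell's taxa are dropped — except tip branches, so a single-taxon cell
keeps its terminal branch. On a unit-branch star tree the two
conventions coincide and PD = TR, PE = WE, which the tests assert.
Polytomies are accepted as-is (all metrics are well defined on
multifurcations) and zero-length branches are retained, contributing 0
everywhere.

The equal-branch-length comparison tree used by RPD/RPE sets every
counted branch to `total / n_branches`, preserving total length to
within 1e-9 relative tolerance. Equalization changes neither topology
nor presences, so the comparison PE reuses the same branch ranges
`R_b`.

## The null model

The randomization preserves each cell's richness and each taxon's
range size exactly. The sampler is a curveball trade chain: pick two
cells, and uniformly re-deal the taxa not shared between them. The
constraints — not any particular sampling algorithm — are the contract;
curveball was chosen because every trade preserves both margins by
construction and the chain mixes quickly on sparse incidence matrices.
Each replicate runs an independently seeded chain from the observed
matrix with burn-in `burn_in_swaps_factor × n_presences` trades
(default factor 1.0, comfortably above the `O(n log n)` mixing
heuristic for the matrix sizes involved); acceptance counts are kept
as a chain diagnostic. The trade loop is compiled with numba and backs
`randomize_matrix`, the null ensembles, and `simulate_null_dataset`
(which first checks the Gale–Ryser feasibility condition and builds a
greedy realization), so all sampling flows through one kernel.

P-values are `(1 + count)/(1 + n_reps)` with ties counted toward
significance in both tails: p is never 0, and ties make the test
conservative rather than liberal. Two-tailed tests split α evenly per
tail. Null RPD/RPE values are ratios of quantities recomputed on each
randomized matrix, not ratios of null summaries. Ties are detected
with a relative tolerance of 1e-9 so that only genuinely identical
recomputations tie, not float jitter. No multiple-testing correction
is applied across cells.

## CANAPE

Step one defaults to PE on the actual tree (the literal two-step
description); `either_tree=True` passes a cell when PE on either the
actual or the comparison tree is significantly high, the rule of the
method's source formulation. The recovery experiments use
`either_tree=True` as the package's own choice: a concentration of
short-branch endemics carries little actual branch length, and is
visible in step one mainly through the equal-branch-length comparison
tree, so the actual-tree-only rule has structurally low power against
neo scenarios. Categories are assigned in the order paleo, neo, mixed,
super-upgrade; they are mutually exclusive and exhaustive by
construction.

## Beta diversity and clustering

Phylo-jaccard uses the same tips-to-root branch sets as PD, so shared
ancestry counts as shared signal; on unit star trees it reduces to
classical Jaccard on taxon sets (tested exhaustively at small sizes).
Average-linkage agglomeration is delegated to
`scipy.cluster.hierarchy.linkage(method="average")` after sorting item
ids lexicographically, which makes tie-breaking deterministic and
biased toward the smallest ids. `cut_clusters(k)` removes the k−1
highest merges and labels clusters 1..k by their lexicographically
smallest member, so labels are stable across runs. The number of
displayed clusters is a user parameter; no attempt is made to infer
it.

## Cross-taxon comparison

Standardization is per group by default (each group's own min/max over
its materialized cells); a pooled mode shares one min/max across
groups. A constant surface standardizes to all zeros with a warning.
`mean_all` averages the groups materialized in each cell rather than
imputing 0 for absent groups — imputation would conflate sampling gaps
with true absence of diversity. Concordant cells require a *nonzero*
standardized value in every group, so each group's minimum cell (which
standardizes to exactly 0) is excluded by construction; the
leave-one-out variant reports the change in concordant cell count,
which is provably non-negative.

## Fuzzy map comparison

The neighborhood-tolerant similarity is this package's own transparent
construction in the spirit of fuzzy raster-comparison toolkits — it is
*not* a replica of any proprietary implementation. Local similarity is
the relative difference `1 − |u−v| / max(|u|,|v|)` (1 when both are 0);
each cell takes the best membership-weighted match within the search
radius, with linear decay from 1 at distance 0 to 0 at the radius
(constant decay optional); the two directional scores are combined by
min, and the scalar similarity is the mean over mutually materialized
cells. The default radius is 100 km, reading "a 200-km-diameter
circle" as a circle of 200 km diameter; the phrase is ambiguous and
the radius is configurable. Distances are Euclidean between cell
centroids. Group dissimilarities (1 − similarity) are computed on
standardized surfaces by default, for cross-group comparability.

## Synthetic data

The generators supply the statistical structure the analysis assumes,
not ecological realism:

- **Trees**: pure birth (Yule), exponential waiting times, default
  birth rate 1. This creates the branch-length heterogeneity the
  relative metrics need; no extinction, dating or calibration. The
  pre-split lineage becomes the root stem.
- **Ranges**: discs in cell space with lognormal radii. Defaults — a
  20 × 10 grid of 25 km cells and radii with median 2.5 cells (~62 km),
  log-sd 0.6 — describe range sizes typical of continental-scale
  occurrence compilations and give mean per-cell richness around 6–10
  for 64 taxa, so rank tests are not dominated by tiny-support ties.
  `center_clustering > 0` draws centers from a 4-component Gaussian
  mixture, producing the spatial autocorrelation the beta-diversity
  stage assumes.
- **Endemism scenarios**: new tips grafted at a random point on a
  random branch (the base tree and matrix are untouched, so they
  remain usable as controls). Tip lengths are drawn from the upper
  half (median..max) of the existing tip-length distribution and
  multiplied by `branch_scale`; with scale ≥ 10 the injected branch
  lands in the top length decile. Ranges are exactly `range_cells`
  cells containing the targets plus nearest neighbors.

What passing tests show: the metrics implement their definitions
exactly (oracle equivalence), the null model preserves its constraints
exactly, type-I error sits at the nominal α under the null process,
and injected neo/paleo concentrations are recovered. What they do not
show: behavior under real-world sampling biases, taxonomic error,
range shapes far from discs, or phylogenetic uncertainty — none of
which the generators emulate.

## Experiment sizes and tolerances

The calibration and recovery experiments run at 64 taxa, a 20 × 10
grid (~170–200 materialized cells), 999 trials, and 20 outer seeds —
large enough for stable rates while keeping a full run in minutes on
one CPU. Calibration test tolerances were fixed a priori from binomial
Monte-Carlo error with a design-effect allowance for within-dataset
correlation: ±0.02 around the 0.05 levels and ±0.008 around 0.01.
Observed rates sit slightly below nominal (e.g. ~0.042 for the
two-tailed PD test), the expected signature of tie-inclusive
permutation p-values on cells with few taxa; the direction of the
deviation is conservative.

## Known limitations

- The sampler's burn-in is a heuristic; extremely dense or nearly
  degenerate matrices (few feasible states) mix slowly, though the
  margin constraints hold regardless.
- `mean_all` over few groups is sensitive to a single group's
  standardization extremes.
- The fuzzy comparison is O(cells²) per pair of groups.
- Cell ids are grid indices, not geographic identifiers; joining
  results back to external GIS layers is left to the exported
  centroids/GeoJSON.
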