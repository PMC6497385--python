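# Methods

This note documents the models and procedures implemented in `herpatlas`,
the parameters that matter, the deliberately fixed conventions, and what
the synthetic test system does and does not demonstrate.

## Coordinate frames and grids

Input coordinates are WGS84 decimal degrees.  Every metric operation
(distances to land-cover classes, convex-hull areas, polygon
intersections, the 2-km gap-analysis grid) happens after an equidistant
cylindrical projection centred on the study-region centroid:
`x = R cos(φ₀) Δλ`, `y = R Δφ` with `R = 6,371,008.8 m`.  Meridian
distances are exact and the map is linear in (λ, φ), so area *ratios* —
everything the gap analysis reports — transfer exactly between frames.
The trade-off is an east–west scale error growing with distance from the
central parallel; at country scale (±1° of latitude) it is below 0.1 %.

Grids are anchored at integer multiples of the cell size from (0° E,
0° N), so grids built over different extents share cell indices for
shared cells.  Cell membership is half-open with west and north edges
inclusive; a floor with a 1e-12 relative snap-to-integer guard makes
edge-point assignment identical across independently snapped grids while
still rejecting points genuinely outside the extent.  Raster row 0 is the
northernmost row.

The atlas grid is 10 arc-minutes (≈18 km); analysis rasters are ≈1 km;
the gap-analysis fine grid is 2 km in metric space (4 km² cells, the
resolution recommended for area-of-occupancy estimates).

## Climatic space

The climatic space is the standardized 19-variable bioclim matrix over
all valid pixels, decomposed by SVD — a correlation-matrix PCA, because
the variables mix °C, mm and dimensionless indices.  Component signs are
fixed by making the largest-magnitude loading positive.

Climatic clusters are axis-parallel bands in the PC1×PC2 score plane.
Each of the first two components contributes
`ceil(explained_fraction / quota)` bands (quota 0.20 by default, so a
component explaining 48 % of the variance yields three bands, each
carrying ~16 % ≤ 20 %).  Band edges are placed at cumulative
squared-score quantiles, so every band carries an equal share of the
component's score variance; scores equal to a cut fall in the lower band,
which makes the partition pixel-order invariant.  Clusters are the
non-empty Cartesian band combinations, renumbered by pixel count
descending.  With two informative components of explained fractions
around (0.6, 0.4) this yields the familiar 3×2 = 6-cluster geometry.
The per-cluster "% sampled" statistic is the fraction of the cluster's
~1-km pixels holding at least one record — the only reading of that
statistic consistent with published values of a few percent for
thousands of observations.

Species ecological profiles use half-open 100-m elevation bins
(`[k·100, (k+1)·100)`), per-record BIO1/BIO12 values, and per-land-cover
class distances computed with a Euclidean distance transform scaled to
metres; classes absent from the raster yield missing distances.

## Distribution models

Predictors are exactly four co-registered layers: the two harmonic NDVI
components and BIO1/BIO12.  The NDVI summary is the least-squares fit of
`y_t = a₀ + a₁cos(2πt/T) + b₁sin(2πt/T)`; component 1 is the mean level
`a₀` and component 2 the annual amplitude `√(a₁²+b₁²)`, which is
phase-free by construction.

The classifier is a one-hidden-layer perceptron: 4 logistic hidden units,
logistic output, weights initialised uniformly in [−0.5, 0.5] from a
seed.  Training is full-batch gradient descent on the *summed*
cross-entropy at rate 0.01 for 2,000 iterations — the classical batch
backprop convention, under which the step size does not shrink with
sample count; with the four standardized predictors this converges to
high-discrimination solutions within the stated iteration budget.  A
`burn_in` setting (default 5) discards the first recorded loss
evaluations from the stored trace and deliberately has no effect on the
final weights.  Degenerate (single-class) training labels are an error.

Pseudo-absences: 5 per presence, drawn uniformly without replacement from
valid pixels that are not the species' own presence pixels, split half
below and half at-or-above 500 m elevation (odd totals favour the low
class by one); a class short of candidates hands its deficit to the
other, with a warning.  Species are modelled only with ≥5 duplicate-free
presence pixels; below that they take the convex-hull fallback.

The ensemble runs `replicates` (default 100; the synthetic scenario uses
10) stratified 75/25 train/test splits, each split drawn per class so
neither side can lose a class.  AUC is the rank-sum (Mann–Whitney)
formulation with ties counted ½.  The binary range thresholds the mean
suitability at the minimum value predicted on any presence pixel
(inclusive ≥, so all presences are inside), then keeps only
8-neighbour-connected components containing a presence.  Both choices —
the inclusive comparison and diagonal adjacency — are fixed conventions
declared here because "contiguous" alone does not determine them.

## Phylogenetic diversity and distinctiveness

PD is rooted: the score of a species set is the branch-length sum over
the union of tip-to-root paths, so a single-species cell carries the full
depth of its lineage.  Internally a boolean tip×branch incidence matrix
makes repeated cell and null-draw evaluations a masked sum; a separate
brute-force path-union implementation serves as the test oracle.

The PDses null preserves richness: `n_draws` (default 10,000; 1,000 in
the synthetic scenario) uniform draws without replacement from the native
species pool, vectorised as random-argsort permutations.  The effect size
is `(PD_obs − mean)/sd`; the p-value is two-tailed with the
`(r+1)/(n+1)` rank convention, flagged at α = 0.05.  A community equal to
the whole pool is degenerate (sd = 0) and reports ses 0, p 1.  Under the
null this machinery rejects at ~4.8 % — slightly conservative, as the
discrete rank test must be.

Fair-proportion ED divides each branch equally among its descendant tips;
the per-species values sum to the total tree length (a conservation law
the tests enforce on random trees).  Category cutoffs are 48 and 96 my
with the boundary values in "medium".  Per-cell ED is the unweighted mean
over the species present, which deliberately reproduces the known
artefact that a cell with a single high-ED species scores extremely high.
Pruning to the native species suppresses unifurcations (summing branch
lengths) but always retains the root, preserving patristic distances and
root-to-tip depths exactly.

## Gap analysis

AOO is the count of unique occupied 2×2 km cells × 4 km².  SPD counts
fine cells whose *centre* samples a TRUE pixel of the binary range
(boundary points count as inside for the convex-hull fallback); the
centre rule is a declared choice where any-overlap would also have been
defensible.  Protected percentages use exact polygon intersection between
the union of a species' cells and the union of protected-area polygons —
partially covered cells count pro rata — and are classified against the
17 % and relaxed 12 % coverage targets.  AOO > SPD is possible (records
outside the modelled range) and is logged rather than asserted away.
Reported percentages are formatted to one decimal, rounding half away
from zero; all computation keeps full precision.

## Synthetic study systems

The generator builds a flat 2°×2° world (declared in `crs_tag`): a DEM as
a smoothed Gaussian field plus an eastern mountain ridge; BIO1 falling
with elevation at a 6.5 °C/km lapse rate; BIO12 rising with elevation;
17 further bioclim layers as correlated transforms of the two plus noise;
a 24-sample annual NDVI cycle whose amplitude tracks precipitation; and a
nine-class land cover from DEM/precipitation thresholds.  The species
tree is pure-birth (Yule), rescaled to a 150-my crown age.  Niche centres
evolve by Brownian motion on the tree in the z-scored (BIO1, BIO12, DEM)
space; per-species breadths are uniform in [0.5, 2] z-units; the true
range is the top decile of the species' suitability surface.  Occurrences
are drawn inside true ranges with probability ∝ suitability × a smooth
effort surface and jittered within the pixel; a configured number of rare
species receive four records to exercise the convex-hull path; an
`exhaustive` mode emits one record per range pixel for exact-recovery
tests.  Protected areas are random rectangles accreted (and the last one
shrunk) to land on a target coverage of 16.6 % of the extent; per-species
true protected fractions are computed by exact per-pixel polygon cover.

Default scenario size is 200×200 analysis pixels, 20 species, 50–80
records per species, 10 model replicates and 1,000 null draws — chosen so
a complete end-to-end run takes tens of seconds on one CPU while leaving
the published scale (100 replicates, 10,000 draws) one config change
away.

What passing on this system shows: the pipeline recovers known richness,
PD and ED maps exactly under dense sampling, recovers narrow-niche ranges
with Jaccard ≥ 0.6 and AUC well above the 0.75 quality bar, matches
analytic protection fractions, and is byte-deterministic under a fixed
seed.  What it does not show: robustness to the pathologies of real
atlas data — spatially structured coordinate error, taxonomic drift
between sources, strong detection covariance with climate, non-Gaussian
niches, or range boundaries set by dispersal and biotic interactions
rather than climate.

## Numerical conventions

Ultrametricity is checked at 1e-6 relative tolerance and violations warn
rather than fail (PD and ED are well defined on any rooted
length-bearing tree).  Convex hulls use Andrew's monotone chain with
strictly-positive cross products, so collinear inputs raise a degeneracy
signal instead of returning silent zero areas.  Per-replicate and
per-stage seeds derive from the master seed by fixed offsets and
`SeedSequence` spawning; identical configuration and seed give
byte-identical CSV outputs.
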