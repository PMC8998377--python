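# Methods

This note documents the models, the defaults and the judgment calls in
`landrisk`, in the order the pipeline runs them.

## Rasters, patches and units

Land-use maps are integer-coded rasters on a square grid (row-major, origin
top-left, values at cell centers); a boolean nodata mask defines the study
region and propagates through every operation. Two grids are *aligned* iff
they share shape, cell size and mask; all two-epoch operations require it.

Patches are connected components per class. Connectivity defaults to 8
(corner-touching cells join a patch), the common convention of
landscape-metrics software; 4 is available. Perimeter counts every exposed
cell edge — against another class, the mask, or the raster boundary — times
the cell size. Both choices matter for the fractal dimension and are
config-visible because different GIS tools disagree on them.

Areas are kept in hectares inside the metric formulas and reported in km²
in tables. This is not cosmetic: the separation index ½√(nᵢ/A)(A/Aᵢ) is
dimensionless only per convention, and the published values it is checked
against reproduce only when A and Aᵢ are in hectares.

## Pattern metrics and the risk index

Fragmentation Cᵢ = nᵢ/Aᵢ, separation Nᵢ = ½√(nᵢ/A)(A/Aᵢ), fractal dimension
Fᵢ = 2·ln(Pᵢ/4)/ln(Aᵢ) with Pᵢ in meters and Aᵢ in m² (a square patch gives
exactly 1; values outside [1, 2] are clipped with a warning). Fᵢ uses
class-total perimeter and area; a per-patch area-weighted variant would need
per-patch bookkeeping and is out of scope. Disturbance Eᵢ = aCᵢ + bNᵢ + cFᵢ
with default weights (0.5, 0.3, 0.2), the conventional weighting that
emphasizes fragmentation. Vulnerability ranks (water 5, cultivated/orchard
4, grassland 3, forest 2, construction 1) are normalized by their sum by
default (Σ Vᵢ = 1); max-normalization is an option. The choice shifts every
loss index Rᵢ = Eᵢ·Vᵢ by a common factor and therefore the absolute grade
thresholds, so it is explicit in configuration.

Metrics of an empty class are absent (NaN), never zero. A silent zero would
deflate the unit risk index; instead an absent class simply contributes
nothing to the mixture and a *present* class with no loss index is an error.

Unit risk ERIₖ = Σᵢ (A_{ki}/A_k)·Rᵢ supports two metric scopes. In
`per_unit` scope (default for mapping) Cᵢ, Nᵢ, Fᵢ are recomputed inside each
unit with the global vulnerability ranks, so the map reflects local pattern.
In `landscape` scope one global metric table feeds every unit, which is the
mode that reproduces whole-landscape summary tables and makes ERI invariant
to the unit tiling when a single unit covers the region. Edge units are
kept when at least 50% of their cells are inside the mask (configurable);
their composition uses their true inside area.

One caveat worth knowing: with per-unit or landscape metrics *recomputed*
after a change, converting forest to construction does not always raise the
index — merging scattered construction into one compact block can lower
construction's separation faster than forest's metrics rise. The monotone
statement that holds exactly is the convexity one: with the loss indices
held fixed, shifting unit composition from a lower-R to a higher-R class
strictly raises ERIₖ. The tests assert that form.

## Kriging and grading

Ordinary kriging with a spherical variogram interpolates unit ERI values
(sampled at unit centroids) to the cell grid. The variogram is fit by
binned method-of-moments with least squares over a coarse range grid;
nugget defaults to 0, making the interpolator exact at the centroids (the
test tolerance is 1e-6). Duplicate centroids make the system singular and
are rejected. Fewer than 10 units falls back to piecewise-constant fill so
toy landscapes still run.

Risk grading uses Jenks natural breaks: the exact O(k·n²) dynamic program
minimizing within-class sum of squares, validated against exhaustive
enumeration for small n. Fields larger than 2000 cells are broken on an
evenly spaced quantile sample of the sorted values (the DP is quadratic and
the breaks of a 40k-cell surface are indistinguishable from the sample's at
mapping precision). Published grade thresholds can be frozen in config for
cross-study comparability instead of recomputing per run.

## Land-expansion analysis (LEAS)

Expansion of class k is the cell set that became k between two epochs.
Training samples are *balanced*: every expansion cell is an eligible
positive, negatives are drawn uniformly from the remaining cells, and the
two sides are equal-sized, with the total sized by the sampling rate
(default 1% of unmasked cells) and shrunk when expansion is scarce.
Balancing keeps the forest's probability output calibrated and makes chance
performance 0.5, which the null-model test relies on. A random forest (100
trees, √-features, out-of-bag scoring, fully seeded) is fit per class and
predicts a growth-probability surface on all unmasked cells plus driver
importances. A class with no observed expansion gets a zero surface and a
logged notice rather than an error: absence of evidence for growth is a
valid training outcome.

## Cellular automaton (CARS)

Per iteration and class: neighborhood effect Ω = (count of the class in a
3×3 window, center excluded)/8 × class weight (default weights: construction
1.0, forest 0.8, cultivated and grassland 0.5, water 0.1; orchard 0.5,
interpolated between cultivated and forest since the scheme leaves it
unstated). Overall probability follows the two-branch seeding rule: where
Ω = 0 and a uniform draw r < P, the cell may *seed* a new patch with
OP = P·(r·μ)·D (μ the patch threshold, default 0.1); otherwise OP = P·Ω·D.
A candidate class per cell comes from a roulette wheel over OP; the
conversion is admitted only if P exceeds the decaying threshold τ = δ^d·r1
(δ = 0.5, r1 ~ U(0.9, 1.1), a unit-mean jitter) and the binary transition
matrix allows it — checked against both the cell's current and original
class, so chained conversions cannot realize a forbidden input→output pair.

The inertia coefficient D is described only verbally in the PLUS-model
literature; the implementation here is a **reconstruction**: D resets to 1
when a class's demand gap closes or shrinks, is multiplied by the capped
gap ratio (≤2 per step) when an under-supplied gap widens, and divided
likewise when an over-supplied gap widens (floor 0.01). Every iteration's
D, τ, gaps and conversion count go to the audit log.

Conversions are demand-balanced: a cell converts only from an over-supplied
class to an under-supplied one, acceptance is greedy by OP and capped at
each class's remaining gap, so total area is conserved exactly at every
iteration and the total absolute gap is non-increasing. The decay counter d
increments whenever an iteration improves the total gap by less than the
step size (0.1% of cells), so a stalled run lowers τ geometrically until
residual demand can be placed; runs that still cannot converge raise an
explicit error carrying the residual gaps and audit. Stop criterion:
every class within 0.1% of cells of its demand, or 500 iterations.
Restricted cells are excluded from the active set and asserted bit-identical
on output. Identical seeds give bit-identical runs.

## Scenarios and demand

Demand is projected by a Markov chain: the row-stochastic transition-rate
matrix estimated from the two observed epochs is applied to the later
epoch's areas, conserving total area. Scenario encodings: economic
development multiplies the five conversions into construction by 1.4;
ecological protection multiplies forest-out conversions by 0.5, conversions
of grassland/orchard/water into forest by 1.3, and the *listed* conversions
of cultivated/orchard/grassland/water into construction by 0.8, and
restricts water cells from any change; natural development is a pass-through.
All rules are pairwise over explicitly listed class pairs — in particular
the −20%-into-construction list does not include forest, so forest→
construction carries exactly the −50% factor and no rule-overlap question
arises for the built-in scenarios. For user-defined specs with wildcard
(class-wide) rules, resolution defaults to most-specific-wins with a
compose-all option.

Multipliers act in two places, deliberately consistently: on the growth
probability surfaces (cell-wise by the donor class, clipped to [0, 1]) and
on the off-diagonal Markov rates before demand projection (diagonal absorbs
the slack; if scaled off-diagonal mass reaches 1 it is renormalized to
0.999). Adjusting demand as well as allocation is a reconstruction — the
scenario definitions speak of conversion probabilities only — but without
it the CA's hard demand constraint would erase the scenario signal from
final areas.

## Synthetic data

The generator builds epochs by seeded region growing: per-class seed counts
are budget/patch-scale, frontiers grow in randomized round-robin until class
budgets (cell-exact) are met, enclosed classes reseed. Patch scales default
to a two-orders-of-magnitude contrast (forest ~4000 cells/patch,
construction ~12), reproducing the qualitative structure of real
mountainous landscapes where forest is a few huge connected patches. The
default fixture is 200×200 cells at 30 m (36 km²) with class shares
proportional to the Hainan central-mountainous-area 2000 composition
(forest 74%, orchard 10%, cultivated 8%, grassland 6%, water 0.7%,
construction 0.4%).

Drivers: elevation is a smooth Gaussian random field, slope its gradient
magnitude, road/river/town distances are Euclidean distance transforms of
generated transects, the water class, and the construction class, and
population/GDP decay exponentially with town distance times smooth noise.
Distance-to-town, population and GDP are therefore strongly correlated by
construction — as their real counterparts are — which is realistic but
means driver-recovery experiments use elevation, the one driver independent
of the class layout, as the programmed signal. Change rules convert an
exact cell budget per rule, drawn by Gumbel-top-k weighted sampling with
logistic weight in a named z-scored driver, recording ground truth.

What the synthetic data does *not* emulate: real class geometry (no
terrain-conditioned land-use layout), spatial autocorrelation of change
beyond the driver dependence, multi-epoch temporal consistency, or
registration/classification noise in the source maps. Passing tests
demonstrate that the algorithms recover programmed structure and honor
their contracts, not that the index values or simulated areas of any real
region are reproduced — the original study's rasters are not publicly
deposited, so its map-dependent numbers are out of reach by construction.

## Problem sizes and determinism

Test and demonstration runs use 80–200 cells per side, 20-seed replicate
batches for the stochastic claims (driver recovery, hindcast-beats-null,
patch-count growth), and a 50-grid randomized batch for the brute-force
oracle equivalence; these sizes make the full suite run in well under a
minute while leaving every statistical bar (≥90–95% of replicates) at its
stated level. All randomness flows through `numpy.random.default_rng`
seeds; identical seeds give bit-identical landscapes, samples, forests and
CA runs.

## Known limitations

- The inertia rule and the scenario-demand adjustment are reconstructions
  (flagged above); alternatives would change convergence speed and the
  magnitude (not the direction) of scenario contrasts.
- The fractal dimension of a class cannot be cross-validated against the
  published table because class perimeters are not printed there.
- Kriging fits a single isotropic spherical variogram; no anisotropy, no
  model selection.
- The CA treats demand as hard constraints; genuinely infeasible demand
  (e.g. a growing class whose growth surface is identically zero) ends in
  an explicit non-convergence report rather than a partial allocation.
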