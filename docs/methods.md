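# Methods

This note documents the models, the defaults and the genuinely open design
choices behind each stage, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Raster model and I/O

A `Grid` is a 2-D array with square cells, the map coordinate of the outer
corner of the top-left cell (row 0 is northmost), and an optional nodata
sentinel. Two dialects are supported: single-band GeoTIFF, with
georeferencing carried in the ModelPixelScale/ModelTiepoint tags and nodata
in the GDAL_NODATA tag, and Esri ASCII grid. Cell addressing is 0-based
(row, col); geographic export converts to cell centres, which pins down the
half-cell convention once for corridor and node coordinates. Layers entering
a pipeline run must agree in shape, cell size and origin; origins within
half a cell are snapped to the first layer, anything larger raises rather
than resampling silently. The projection label is metadata only — no
geodesy is performed.

## Synthetic landscapes

The generator produces the statistical structure the analysis assumes, not
any real geography:

- **Terrain**: midpoint-displacement (diamond–square) relief with amplitude
  proportional to the roughness parameter, added to a fixed west-high →
  east-low linear trend (400 m → 80 m). As roughness → 0 the surface
  collapses onto the trend, which gives a clean limit test.
- **Land cover**: a Gaussian random field (white noise smoothed with σ =
  autocorrelation range, default 6 cells) blended 55/45 with standardized
  elevation, sliced at quantiles so the configured class proportions are
  realized exactly before overlays. Classes are stacked in a fixed
  low-to-high affinity order (water and paddy on low flat ground, grassland
  and woodland on high ground). A sinuous west–east river (water flanked by
  bottomland) and a circular urban core (construction) are stamped on last,
  so realized fractions stay within a few points of the targets.
- **Multi-date series**: per-cell targets are drawn independently from the
  transition-matrix row of the current class, which makes empirical
  transition frequencies converge exactly to the matrix. Spatial contiguity
  is imposed afterwards *within* each source class by routing a λ-share
  (default 0.5) of the drawn conversions to the cells with the most
  8-neighbours already in the target class; permuting targets within a
  source class cannot change the per-class transition counts, so the
  marginal statistics survive the patchiness bias. This also makes the
  series consistent with the Markov demand projection by construction,
  which the parameter-recovery tests exploit.

Default demo conditions: 220 × 300 cells at 90 m (≈ 20 × 27 km), three
dates, seed 42. The coarser-than-source cell size keeps the default 10 km
corridor-length filter meaningful on a grid that every stage processes in
seconds. What the generator does **not** emulate: realistic drainage
topology in the DEM, road networks, calibrated class geometry of any real
region. Passing tests therefore demonstrate correctness of the algorithms
under controlled statistical structure, not predictive skill on real
landscapes.

## MSPA

Classification uses chamfer (8-neighbourhood/chessboard) distances, the
standard deterministic approximation in raster MSPA practice. The map edge
is treated as background. With edge width `w`:

core = foreground farther than `w` from background; edge/perforation =
non-core foreground within `w` of core, split by whether the nearest
background is border-connected (edge) or an enclosed hole (perforation),
ties to edge; the remaining foreground forms connector components, typed by
the core components holding cells within chessboard distance `w + 1`:
none → islet, two or more → bridge, one → loop when the contact cells of
that core fall in ≥ 2 connected clusters, else branch.

Known limitation: a connector that wraps a core completely has one
*connected* contact zone and classifies as branch rather than loop; the
rule is deliberately local and shared verbatim by the brute-force test
oracle. Foreground connectivity is a parameter (default 8, with background
connectivity complementary); published tool settings such as "transition"
or "intext" flags affect display only and are not modelled. The seven codes
always partition the foreground exactly, core area is non-increasing in
edge width, and the classification is equivariant under rotation and
mirroring — all enforced by tests against an independent per-cell BFS
oracle on small grids.

## Connectivity indices

Patch distances are edge-to-edge approximations: minimum cell-centre
distance minus one cell size, floored at zero (exact polygon distance would
be an alternative; the approximation is deterministic and cheap).
`S_L` defaults to the summed area of the analysed patch set and can be
overridden with a study-area total; importance rankings are invariant to
that choice. The dispersal kernel is the negative exponential calibrated so
`p = probability_at_threshold` (default 0.5) exactly at the threshold
distance; best-path products are computed by Dijkstra on −log p weights
over the threshold graph. During removal experiments `S_L` is held fixed,
so `dΦ` (reported ×100, in percent) is a pure connectivity-loss measure —
this is what makes the `dPC > 1` selection rule meaningful. The threshold
sweep reports indices and mean/max importances per threshold; "optimal"
threshold selection is left to the user, with a documented heuristic
(smallest threshold at which the top-k dPC ranking stabilizes) available.

## Resistance surface

AHP weights come from the principal eigenvector of a positive reciprocal
comparison matrix (power iteration, tolerance 1e-10), with the consistency
ratio computed from Saaty's RI table and a warning above 0.1. Defaults are
the published coefficients: MSPA core/islet 10, edge/bridge 20, branch/loop
30, perforation 40, background 80; land cover woodland 10 … construction
100; elevation 10/20/40/70/90 at breaks 150/300/600/1000 m; slope
10/20/40/60/80 at 5/10/30/45°; weights 0.5638/0.2634/0.1178/0.055.
Elevation and slope default to the fixed printed breaks; a natural-breaks
mode (exact Fisher–Jenks dynamic program on a ≤ 2000-value subsample) is
available since terrain grading by natural breaks is common practice.
Composition is the weighted arithmetic mean clamped to [1, 100] — the
standard weighted-overlay reading; a multiplicative overlay would change
scale but not ordering. The grading configuration is hashed into the run's
provenance sidecar.

## Corridors and gravity

Movement cost between 8-adjacent cells is the mean endpoint resistance ×
step length (1 or √2) in *cell* units, so cumulative cost is
resistance × distance and scales linearly with any rescaling of the
surface; geometric length is reported separately in km. Cost distance is
exact multi-source Dijkstra on the sparse cell graph. Per pair, the path is
backtraced from the cheapest destination-patch cell. Filters: geometric
length below the minimum (default 10 km), then near-duplicate removal at
≥ 90 % cell overlap on the smaller set, keeping the cheaper path (the
overlap criterion is a package choice; only "duplicated paths" is specified
upstream). The gravity model is implemented in its closed form
`G = L_max² ln(a_i) ln(a_j) / L_ij²`; areas enter in hectares by default so
logarithms stay positive (the unit is a config knob — the printed tier
bounds 1/10/100 are only meaningful relative to the unit the analyst
adopts). Tier assignment is strict at the upper bound: `G = 100` is level
2. Because `L_max²/L_ij²` is scale-free, tiering is invariant to uniform
scaling of the resistance surface.

## Hydrological nodes

Depression filling is priority-flood (exact, idempotent). D8 directions
take the steepest drop/step-length with a fixed tie priority
(E, SE, S, SW, W, NW, N, NE); flats drain by breadth-first propagation from
their lowest resolved neighbours, so every interior cell has exactly one
direction and total accumulation is conserved (Σ over outlets of
accumulation + 1 = cell count). Valley lines are cells at or above the 0.95
accumulation quantile (the extraction threshold is a package choice — no
published rule exists); ridge lines apply the same rule to the negated
surface. Node typing intersects 1-cell-dilated rasters (thin raster lines
make exact cell equality brittle) and merges hits within 3 cells by
union-find, placing each node at its cluster centroid — order-independent
by construction. The strategic rule defaults to the single maximum-cost
corridor, the literal reading of "the maximum cost path"; applying it to
all corridors is an option. A corridor counts as persistent when ≥ 60 % of
its cells are foreground in every supplied date — a cheap raster proxy for
re-deriving corridors per date.

## Markov–CA

Transition matrices are plain cross-tabulations; demand projection is
`counts × Pᵏ` with largest-remainder rounding so totals conserve exactly.
The cellular automaton replaces the original back-propagation ANN with a
pluggable suitability interface; the default is multinomial logistic
regression fitted on a seeded 1 % cell subsample, normalized per cell.
Allocation converts cells only from surplus to deficit classes — chosen by
seeded roulette over suitability × (3×3 neighbourhood density + 0.01) ×
class inertia, where inertia is adjusted multiplicatively each iteration in
proportion to the remaining relative deficit (a documented simplification of
adaptive-inertia competition, whose exact form is unpublished). Restricted
cells never change; a convertibility matrix can forbid class pairs
(default: all allowed). Total absolute deficit is non-increasing by
construction; iteration stops within a 0.5 % tolerance or at 300 iterations
(3×3 neighbourhood, both published settings). Agreement is Cohen's κ and
overall accuracy from the confusion matrix.

## Network structure

`α = (L − V + 1)/(2V − 5)`, `β = L/V`, `γ = L/(3(V − 2))`; lowercase and
uppercase V in the printed formulas are the same node count, per the
standard index definitions. The cost ratio is `1 − L/C` with `C` the *total*
length of the subnetwork's corridors: the total-length reading reproduces
the published 1.00 and 0.99 cost ratios from the printed corridor lengths,
while a per-corridor reading does not. Reports round half-up to two
decimals. The evaluator emits the three standard pairings (level-1 ×
strategic, level-2&3 × natural, level-2&3 × artificial) plus a whole-network
row; α and γ are flagged undefined below three nodes.

## Problem sizes and determinism

The test suite and drivers run at desk scale: morphology oracles on
≤ 16 × 16 grids, path-enumeration oracles on ≤ 6 patches, relaxation
oracles on ≤ 6 × 6 cost grids, parameter recovery on 200 × 200 rasters, and
the end-to-end pipeline on ~100 × 130 to 220 × 300 grids — sizes chosen so
the full suite completes in seconds while every property is exercised at
the scale its statistics need. All stochastic components consume
`numpy.random.default_rng` generators derived from explicit seeds; a
pipeline run is a pure function of (inputs, config), and repeated runs
produce byte-identical tabular outputs, which the suite asserts.

## Limitations

No reprojection or geodesy; corridors are 1-cell paths without width or
circuit-theory spreading; connector subclasses beyond the seven base MSPA
classes are not implemented; the CA is a deliberately simple competition
scheme, adequate for demand satisfaction and contract testing but not a
calibrated forecast model; and published landscape-scale counts (sources,
corridor totals, node totals) depend on undeposited rasters and are treated
as non-reproducible — only the structural indices derived from printed
counts are golden-tested.
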