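# Methods

## Model

The analysis treats free-roaming village dogs as a disturbance source
whose influence decays with *path distance* — travel distance measured
along the terrain surface — rather than straight-line distance. Dogs
start from "populated areas" and forays extend at most 10,900 m of path
distance; human disturbance alone extends 1,920 m. Habitat inside a zone
is discounted; what remains is *effective habitat*.

Assumptions worth stating explicitly:

* **Isotropic surface metric.** The step cost between adjacent cells is
  `sqrt(h² + dz²)` with `h` the horizontal spacing (`cell_size`, or
  `cell_size·√2` diagonally). No friction surface, no up/down asymmetry:
  climbing and descending cost the same. This is the simplest metric
  combining horizontal and vertical travel; slope-dependent energetic
  costs would change distances quantitatively but not the zonal logic.
* **8-connectivity.** Queen moves on the raster lattice. A 4-connected
  lattice overestimates off-axis distances by up to 41%; the residual
  overestimate of 8-connectivity vs. true Euclidean geodesics is at most
  ~8% (the chamfer-metric bound) and is the standard accuracy of GIS
  cost-distance tools.
* **Exact shortest paths.** The surface is computed by multi-source
  Dijkstra on the explicit cell graph (scipy's `csgraph.dijkstra`,
  `min_only`), which is optimal for non-negative weights — not a
  sweep-based approximation. Tests cross-check it against an independent
  graph implementation (networkx) on enumerated edge lists.
* **Nodata DEM cells are barriers**; paths route around them. Cells
  unreachable from every source get nodata distance and count as outside
  every zone (unreachable by path implies unreachable by dogs under the
  model); their area is reported via a logged warning.
* **Every residence can source dogs.** The populated-area mask makes no
  distinction between households with and without dogs.

## Parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| density window radius | 564.19 | m | circle of exactly 1 km², so the threshold reads "houses per km²" |
| density threshold | 6.25 | houses/km² | strictly-greater cut for populated areas |
| human impact distance | 1,920 | m | edge effect of residences alone |
| dog foray distance | 10,900 | m | maximum observed dog foray (path distance) |
| available sample size | 100 | points | random locations characterizing availability |
| threat breaks | 50 / 165 | km² | low/moderate/high dog-zone habitat tiers |
| avoidance midpoint θ | 10,900 (strong) / 1,920 (weak) | m | logistic use-weight midpoint |
| avoidance softness s | 1,000 | m | width of the logistic transition |

The density threshold is a *strict* inequality ("greater than"); a cell
at exactly 6.25 houses/km² is not populated. Zone membership is
`distance ≤ d`, so effective habitat requires strictly greater distance;
the boundary set has measure zero at raster resolution but the
convention is fixed and documented. Threat tier boundaries assign the
boundary value upward (165 km² is "high") — conservative for a threat
ranking. How the housing-density surface was computed in the original
desktop-GIS workflow is not recorded; the circular moving-window count
with a 1 km² window is this package's choice, and both radius and
threshold are configurable.

## Statistics

`summarize_shift` reports the difference between mean used and mean
available path distance, also expressed in availability standard
deviations (sample SD, n−1). "Two standard deviations" therefore means
the shift divided by the availability SD, not a pooled SD. Distribution
summaries are binning-free; histograms (2-km bins) appear only in plots.

`fit_avoidance` is an extension beyond the headline statistics: used
distances are modeled as availability re-weighted by the logistic
`w(d) = 1/(1+exp(−(d−θ)/s))`, with availability approximated by a
20-bin empirical density over the pooled distance range. The likelihood
is maximized by a fixed coarse grid over (θ, log s) followed by
Nelder-Mead refinement, so the fit is deterministic. When use equals
availability the likelihood is flat in the no-selection limit (θ below
the data or s beyond the data range); the fit reports whatever flat
parameterization the grid prefers, which is why the no-selection test
checks weight flatness rather than parameter values. Degenerate inputs
(all distances equal, too few points) raise `FitError` rather than
returning a silent answer.

`jenks_breaks` implements Fisher's exact dynamic program for optimal
1-D classification (global minimum of within-class sum of squares), not
the common heuristic reseeding variant. Ties between equally good
partitions resolve toward the smallest first break. Break values are
midpoints between adjacent class-boundary values. Fixed 50/165 km²
breaks and re-derived Jenks breaks are separate modes, never mixed
silently.

## Synthetic landscapes

The generator exists because the field inputs are restricted; it
reproduces the *structure* the analysis depends on, not any particular
place:

* **Terrain** (`generate_terrain`): a settled lowland apron rising to a
  high crest ring with high interior valleys behind it, plus low-
  frequency random cosine texture and radial valley corridors carved
  from mid-slope past the rim; elevation is rescaled to span exactly
  `relief_m` (default 2,000 m on a 36 × 36 km grid at 100 m cells).
* **Residences** (`place_residences`): one village per azimuthal sector
  of the outer apron, each drawn from the low-elevation quartile —
  settlements ring the massif along its valley mouths the way villages
  follow roads and rivers. Houses scatter around centers with a 500 m
  Gaussian.
* **Habitat** (`generate_habitat_and_reserves`): the elevation band
  150–1,350 m, mirroring a montane vegetation band that excludes both
  the settled valley floors and the rocky crest. The band splits
  habitat into a near-village apron and a remote interior — the
  bimodal distance structure that produces an availability mean of
  ~5 km with a remote block beyond the foray distance, matching the
  reserve-scale pattern the analysis was designed around. Reserves are
  disjoint jittered rectangles, one per vertical strip.
* **Occurrences** (`simulate_occurrences`): habitat cells with finite
  distance sampled with probability ∝ `w(d)` (scenarios `many_dogs`,
  θ = 10,900 m; `few_dogs`, θ = 1,920 m; `null`, uniform), with
  replacement (sign locations can share a cell), jittered within the
  cell.

Randomness is partitioned per stage (`default_rng([seed, stage_tag])`),
so changing the occurrence seed cannot perturb the terrain, and fixed
seeds give bit-identical landscapes.

What the generator does **not** emulate: real road networks and the
linear settlement ribbons along them, spatial autocorrelation of
occurrence records, observer effort gradients, multi-reserve range
topology, and DEM noise/voids. Passing tests therefore demonstrate that
the pipeline's machinery and statistics behave correctly under the
assumed avoidance process — not that the avoidance model is the true
generating process of any field dataset.

## Numerical choices

* Areas are cell counts × cell area; rasters must share identical
  georeferencing (no implicit resampling — misalignment is an error).
* Value extraction at points is nearest-cell-center, not interpolated:
  the analysis thresholds distances, and interpolation across nodata is
  ill-defined. Points exactly on interior cell edges snap by `floor`.
* Point-in-polygon for rasterization counts boundary centers as inside.
* Nodata is NaN internally; −9999 in ASCII grids, the GDAL_NODATA tag
  in GeoTIFFs (uint8/255 for masks).
* Dijkstra tie-breaks are irrelevant to the distances themselves
  (unique minima of sums of positive weights up to float association);
  the implementation is deterministic throughout.
* The Jenks dynamic program uses prefix sums for O(1) interval SSDs and
  a 1e-12 tolerance when comparing partitions, preferring smaller split
  indices.

## Problem sizes

The default landscape is 360 × 360 cells (129,600 nodes, ~1M edges);
a full pipeline run takes a fraction of a second. The statistical
suites use: 200 null-calibration trials at the reference sample sizes
(46 used / 100 available); 20 seeded runs at 500 used points for
avoidance-midpoint recovery (recovered θ within ±1,500 m of 10,900 m);
and a 10-seed scenario contrast (20 replicates in the acceptance
script, where the extra replicates stabilize the reported medians).

## Known limitations

* The surface metric ignores slope-dependent movement costs and
  directional asymmetry; distances under heavy load or deep snow would
  differ.
* Housing density uses a hard circular window; kernel-weighted density
  would soften populated-area edges.
* The avoidance model conditions on a single covariate (path distance);
  real habitat selection is multivariate, so θ estimates from field
  data would absorb confounded gradients (elevation, bamboo cover).
* Reserve polygons in the generator are rectangles; zonal statistics
  with intricate real boundaries exercise the same code path via the
  polygon rasterizer but with more boundary cells.
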