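# Methods

## Raster model

A DSM is a single-band raster of elevations (m above datum) with a square
pixel, an axis-aligned north-up transform and an explicit nodata mask. Pixel
*centers* carry map coordinates; array indexing is 0-based internally while
tree (row, column) labels are 1-based, matching how plantation rows are
counted in the field. GeoTIFF I/O uses the standard ModelPixelScale /
ModelTiepoint / GeoKeyDirectory tags plus GDAL's ASCII nodata tag, written
and parsed with `tifffile`; an EPSG code round-trips through the
ProjectedCSType geokey. Rasters without geotags are processed in pixel units
with a warning. Nodata pixels are excluded from every statistic; a tree whose
filled crown footprint is more than 20% nodata is flagged unreliable
(configurable), the analogue of discarding badly photo-reconstructed trees.

## Synthetic orchard

The simulator emulates the reference system — a mature, intensively planted,
irrigated olive orchard — well enough to give the pipeline exact oracles, not
to be photorealistic.

**Crowns** are half-ellipsoids raised on a trunk: canopy base `h0` (default
0.6 m — olive skirts are kept ~60 cm off the soil), apex `h0 + c`, horizontal
semi-axes `a, b`. A DSM sees the canopy top only, so the rendered surface
over the footprint is `z = h0 + c·sqrt(1 − (x/a)² − (y/b)²)` and the
DSM-visible volume (surface integral above ground) has the closed form

    V = π a b [ h0(1 − u_l²) + (2c/3)(1 − u_l³) ] − π a b c (2 − 3u_t + u_t³)/3

with `u_l = clamp((skirt − h0)/c)` for a raised skirt and
`u_t = clamp((top_cut − h0)/c)` for a flattened top (no cuts: `u_l = 0`,
`u_t = 1`). Visible footprint area is `π a b (1 − u_l²)`. Property tests
check both against 1 cm brute-force integration to 1%. Mean crown-pixel
height under this model is ~0.72–0.75 of tree height, consistent with the
area/height/volume ratios a DSM pipeline reports for real olives.

**Defaults** (chosen once as field-realistic): apex ~ N(4.0, 0.25²) clipped
to [3.3, 4.5] m; within-row semi-axis U(1.35, 1.75) m (kept below half the
4 m tree spacing so crowns stay separable), across-row semi-axis U(1.6, 2.3)
m (rows are 8 m apart) — projected areas ≈ 7–13 m²; center jitter truncated
N(0, 0.1²) clipped at 2σ, which makes the no-overlap guarantee deterministic.
Default synthetic pixel size is 0.05 m, the same order as centimeter-level
UAV ground sample distances, balancing realism and runtime.

**Terrain** is a plane (default gradient 0.005 in y) plus a low-frequency
Gaussian field: coarse white noise (SD 0.05 m) spline-upsampled at a 20 m
wavelength. A cultivated, deep-loam field undulates gently at tens of meters;
undulation at the scale of a single crown footprint would not be "smooth
terrain" and cannot be recovered by any soil-interpolation scheme.

**Pruning.** *Traditional* and *adapted* remove a volume fraction `f` by
scaling `a, b` by `sqrt(1 − f)` (volume is proportional to `a·b`, so the
removal is exact); defaults `f = 0.36` and `0.42` respectively, the
characteristic severities of the two manual styles, with optional per-tree
spread. *Adapted* may additionally carve a central core gap, but a surface
DSM cannot see an interior gap under an intact canopy top — the gap only
affects the rendering where it breaches the top, a documented physical
limitation, and it is off by default. *Mechanical* clamps the canopy at a
per-tree top cut drawn U(3.5, 4.0) m above the terrain and raises the skirt
to the 0.7 m low cut. Because the 0.7 m low cut sits above the 0.6 m default
canopy base, it trims ~0.1% of the footprint, so "topping does not change
projected area of short trees" holds to ~0.2% rather than exactly. Each
crown records its realized severity (1 − V_after/V_before).

**Regrowth** is horizontal (olives regrow along the horizontal axes after
pruning, not upward): semi-axes scale by `sqrt(1 + g)` with `g` looked up
from the tree's severity class — defaults `{<10%: 0.25, 10–30%: 0.35,
30–50%: 0.60, >50%: 0.80}`, loose field-inspired values, user-settable and
not calibrated — plus optional per-tree lognormal noise. After a year of
regrowth, heavily pruned neighbours can genuinely touch at 4 m spacing; the
delineator then reports a merged component (see below), which is realistic.

**What the simulator does not emulate:** photogrammetric texture and
reconstruction noise structure (only additive Gaussian noise and an optional
artifact injector that deletes crowns / adds spikes, off by default), RGB
content, cover-crop strips, crown asymmetry beyond axis-aligned ellipses.
Passing tests therefore demonstrate correctness of the *measurement chain*
on geometrically clean canopies, not robustness to every failure mode of
real photo-reconstruction.

## Delineation

Tiles use the **population** SD (divide by N): the 0.10 m threshold is only
reproducible once the estimator is fixed, and tiles are complete populations
of their own pixels. The tile grid is anchored at the raster origin.

The border-refinement zone and rule required genuine design decisions:

- **Refinement zone.** Interface tiles alone are not enough at 4 m spacing:
  a tile wedged between two crowns touches no soil tile, yet its soil pixels
  must not weld the crowns together; and on smooth crown tops the apex tile's
  SD can drop below 0.10 m, leaving a spurious interior "soil" hole. Under
  the default rule every tree tile is therefore refined, plus soil tiles
  edge-adjacent to tree tiles (the "both sides of the interface" zone);
  genuine canopy pixels pass the height test and are unaffected.
- **Default rule, `height-above-soil`.** A pixel is tree iff its elevation
  exceeds the local bare-soil surface by more than a margin. The soil surface
  is estimated from non-interface soil tiles by nearest-neighbour fill plus
  Gaussian smoothing (a local DTM), and the margin adapts to how well that
  surface tracks the terrain: `max(0.10 m, 3·SD of soil residuals)`, so DSM
  noise and terrain roughness raise it automatically.
- **Alternative rule, `nearest-mean`.** A pixel is tree iff strictly closer
  to the mean of surrounding tree pixels than to the mean of surrounding
  soil pixels (1.5 m circular windows; ties to soil; with only interface
  tiles refined). This is the more literal reading of "compare to the
  surrounding tree and soil values", but on smooth dome-shaped crowns it
  assigns the low canopy skirt (everything below the midpoint of the two
  class means — 10–19% of a half-ellipsoid's footprint) to soil, and it
  fails entirely when no interior tree tile exists to supply the tree mean.
  It is kept as an option and verified on well-separated crowns.

Components are labeled 8-connected; components under 0.5 m² are discarded as
noise (both parameters). Crowns that merge into one component are reported
as one tree — no implicit splitting — with an optional watershed split seeded
at the configured grid nodes behind a flag (`split_merged`) for dense
canopies.

Refinement is deterministic, and a second pass — with tile labels re-derived
from the refined mask by majority vote — reproduces the identical mask on
clean scenes (the fixed-point form of "refining the refinement changes
nothing").

## Feature extraction

The ground reference is a single per-tree constant — the mean soil DSM in a
1 m Euclidean ring off the crown boundary, excluding pixels of any tree —
kept even on sloped terrain because that is how a buffer-based field protocol
works; on the default gentle terrain the induced height bias is < 1 cm. An
empty ring widens in 0.5 m steps to 3 m, after which the tree is flagged
"landlocked". Heights use the raw crown maximum (faithful to a
maximum-minus-soil protocol); a `height_quantile` option robustifies against
spiky DSMs. Negative per-pixel heights clamp to zero in the volume sum so
soil noise cannot subtract volume. Grid identity: the centroid is rotated
into plantation axes, divided by the spacings and rounded; ties for one node
keep the nearer centroid and flag the other; centroids more than half a
spacing from any node are flagged off-grid. "Central coordinates" are crown
centroids.

On noiseless 0.05 m replicas of the full field the chain recovers all 648
trees with |height error| < 1 cm and area/volume errors < 1%; the acceptance
tests assert the looser 5% / one-pixel oracle bounds.

## Multi-temporal analysis

Matching is by (row, column); only pairs reliable on both dates enter
statistics, everything else lands in the QC report. Percent change is per
tree, later minus earlier over earlier. Treatment tables use the sample SD
(N−1) for deltas — summaries of samples of trees — in deliberate contrast to
the population SD inside tiles. The headline percentage is the mean of
per-tree percentages; the ratio-of-means alternative is also reported, since
the two differ on skewed data and printed tables rarely say which was used.
Severity classes are left-closed half-open intervals ([30, 50) etc.), so a
tree pruned by exactly 30% falls in the higher class. Non-positive baselines
exclude a tree from ratios (logged). No hypothesis testing is performed —
the design this mirrors was a demonstration-strip comparison, not a
randomized experiment.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` with explicit seeds;
derived seeds stay below 2³¹. FFT-based window means treat counts < 0.5 as
empty. The test suite runs the full 648-tree field once (a few seconds) and
otherwise uses 3 x 4 to 6 x 6 orchards; brute-force volume integration uses a
1 cm grid. The acceptance script regenerates the full field and reruns the
whole pipeline in well under a minute.

## Known limitations

- Merged canopies are a single record unless the watershed flag is set;
  after simulated regrowth a few adjacent trees can legitimately merge.
- DSM-visible volume includes the air column under the canopy skirt, as for
  any surface-model method; interior (under-canopy) structure is invisible.
- The buffer-mean ground reference biases heights on strongly sloped terrain
  (the ring averages uphill and downhill soil).
- The nearest-mean border rule under-segments smooth low-skirted crowns; it
  exists for comparability, not as the default.
- Synthetic truth covers geometry only; photogrammetric accuracy percentages
  of real surveys are out of scope.
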