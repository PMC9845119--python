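# Methods

This note documents the models and procedures implemented in `crownmap`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical decisions that make the pipeline
deterministic.

## Crown separation (detect centre and relabel)

**Model assumption.** Tree crowns are approximately round, so the
Euclidean distance transform (EDT) of a binary crown mask has one local
maximum per crown, even when several crowns merge into one connected
blob.

**Stages.**

1. *Distance transform.* Each crown pixel receives its Euclidean
   distance (in pixels) to the nearest background pixel. The image
   border is treated as background: tiles are processed independently,
   so a crown truncated by the tile edge must still get a finite ridge
   rather than an unbounded one.
2. *Centre detection.* A pixel is a centre candidate when its EDT value
   survives an m x m maximum filter unchanged. `m` (odd, default 3)
   controls the minimum separation and should match the smallest object
   to be split — at 0.25 m pixels the minimum mappable crown of 0.25 m²
   is 4 pixels, which a 3 x 3 window resolves. Flat EDT ridges produce
   connected candidate plateaus; each 8-connected plateau collapses to
   one centre, the pixel with the smallest row-major index (any single
   representative is valid; row-major is deterministic).
3. *Relabelling.* Every crown pixel x is assigned to the centre c
   minimising d(x, c) = ||x − c||₂ + λ·B(x, c), where B counts background
   pixels on the discrete line from c to x (Bresenham rasterization as
   implemented by `skimage.draw.line`, endpoints excluded). The penalty
   is additive; λ defaults to the grid diagonal in pixels so that
   crossing even one background pixel is worse than any gap-free
   assignment — effectively a hard constraint that degrades gracefully
   when a region contains no centre at all. Ties go to the smallest
   centre index. λ = 0 reduces the rule to plain nearest-centre
   (Voronoi) labelling.
4. *Hole filling.* Background regions not 4-connected to the image
   exterior and bordered (8-neighbourhood) by exactly one label are
   converted to that label. Gaps between two different crowns and
   corridors open to the tile edge are left untouched, so only
   artificial holes inside single crowns are filled.

**Guarantees.** Before hole filling, the labelled foreground equals the
input mask pixel-for-pixel and the number of labels equals the number of
centres. The pipeline is a pure function of its inputs; the test suite
checks exact (bit-level) agreement with an independent all-pairs /
BFS brute-force implementation on random scenes.

**Known limit.** Crowns overlapping so heavily that their union has a
single EDT maximum are not split — a shape-based criterion cannot see
two objects in one round blob. On heavily clumped synthetic scenes the
recovered instance count is therefore below the true count while
remaining well above the connected-component count.

## Crown geometry, expansion and the hectare grid

Crown area is pixel count x pixel area; crowns below 0.25 m² are
dropped (the smallest crown reliably visible at 0.25 m resolution).
Crown diameter is the equal-area-circle diameter CD = 2·√(A/π). The
centroid (mean of pixel centres, in world coordinates) determines both
the hectare cell and the land-cover class of a tree — a single,
unambiguous assignment, in contrast to majority-overlap rules.

Boundary-weighted segmentation draws crowns systematically about 27% too
small. Two readings of "extend by 27%" differ by ~13% in cover, so both
are implemented: the default *area* mode grows each crown's footprint by
27%, the *diameter* mode multiplies CD by 1.27 (the diameter scaling is
also what the natural-forest allometry applies to CD before predicting
DBH, independent of the cover setting).

Crowns are polygonized on pixel boundaries (no smoothing, bit-stable
areas). For area-mode expansion the buffer radius solves
A + r·P + π·r² = 1.27·A using the polygon's own area A and perimeter P —
for a smooth circle this reduces to r = (√1.27 − 1)·CD/2, but a
rasterized outline is a staircase about 4/π longer than the smooth one,
and the circle-based radius would over-grow every crown's area by ~4.5%.
Because the staircase is also non-convex, the quadratic solution is then
refined by a fixed three Newton steps on the measured buffered area
(derivative = buffered perimeter); the fixed iteration count keeps the
result deterministic. Buffered crowns are dissolved (unioned) before
cover is computed, so overlap is never double-counted.

The hectare grid uses half-open 100 m cells [x, x+100) x (y−100, y] to
avoid double counting on cell edges; density is the centroid count per
cell (1 cell = 1 ha), cover the dissolved-canopy intersection area as a
percentage, carbon the sum of per-tree AGC in Mg. Trees outside the grid
extent are counted in an explicit overflow bin rather than silently
dropped.

## Allometry

**Major-axis regression.** Both CD→DBH relationships are fitted with the
major axis (MA), the errors-in-both-variables line minimising orthogonal
distances: slope = (S_yy − S_xx + √((S_yy − S_xx)² + 4·S_xy²)) / (2·S_xy),
intercept = ȳ − slope·x̄. MA is appropriate because crown diameter and
stem diameter both carry comparable measurement error; it is symmetric
(swapping axes inverts the slope). Two caveats are documented because
they are easy to miss: (i) MA is only scale-equivariant on collinear
data — under scatter, rescaling one axis does not exactly rescale the
slope reciprocally; (ii) when noise sits on one axis only, the MA line
tilts to split that noise between both axes, so the vertical residual sd
recovers a generating noise level only when the predictor spread
dominates the noise (for the log-log forest fit, a CD range of roughly
1–25 m, log-sd ≈ 0.9, is sufficient; a narrow CD range inflates the
recovered sigma by several percent).

`sigma` is the residual sd on the fitted scale: orthogonal residuals for
the linear form, vertical residuals in log space for the log form (the
vertical definition is the one that feeds the Baskerville correction).
Degenerate fits (S_xy = 0, constant x, n < 3) raise immediately.

**Fitting protocol.** The field-table protocol is the average of four
fits, each on a random 50% subsample with a fixed, logged seed (defaults
1–4); coefficients and sigma are averaged arithmetically. The printed
default coefficients are used verbatim as the package's calibrated
models.

**Equations and routing.** Defaults, with DBH in cm, AGB in kg:

| class | CD→DBH | DBH→AGB |
|---|---|---|
| natural_forest | exp(1.154 + 1.248·ln(1.27·CD))·exp(0.3315²/2) | moist-forest: exp[1.803 − 0.976·E + 0.976·ln ρ + 2.673·ln DBH − 0.0299·(ln DBH)²] |
| savanna_shrubland | −4.665 + 5.102·CD | 0.091·DBH^2.472 |
| plantations / farmland / urban_builtup | −4.665 + 5.102·CD | 0.202·DBH^2.447 |

AGC = 0.47·AGB everywhere. The routing table is data, overridable per
call. E (environmental stress) is a per-scene scalar and must be given
explicitly — there is no defensible silent default; ρ (wood density)
defaults to 0.54, an abundance-weighted average for tropical forest
plots. The linear CD→DBH line crosses zero at CD ≈ 0.914 m, so crowns
between 0.25 m² and ~0.66 m² in linear-model classes would predict
non-positive DBH: these trees get AGB = 0 and a `below_allometry_domain`
flag instead of negative biomass, keeping them auditable. Biomass is
strictly increasing in DBH for the power forms everywhere and for the
moist-forest form up to 1,000 cm (derivative 2.673 − 0.0598·ln DBH > 0
there), well beyond any physical stem.

## Stratification

Land cover comes either as GeoJSON polygons with a `class` property or
as a categorical raster with a documented value map (code 0 = nodata).
Classes are restricted to the six supported names; unknown values are
rejected at load. Assignment is by crown centroid; points on shared
polygon boundaries take the first feature in file order (deterministic
and order-stable). Trees outside every feature receive a mandatory
caller-supplied default class plus a flag — synthetic or clipped layers
need not cover the scene. Coordinate frames are compared when both sides
declare one; mismatches raise rather than silently reprojecting.

## Uncertainty

*Bias metrics.* Mean relative error
bias = (1/N)·Σ (Y_obs − Y_pred)/Y_obs × 100 (undefined when any
observation is 0 — raises) and the stock-level form
|Σ(Y_obs − Y_pred)| / |Σ Y_obs|, which is sign-symmetric and
permutation-invariant.

*National uncertainty.* Per-class biases are combined as
Σ w_c·|bias_c| with area weights summing to 1 (checked to 1e-9).
Magnitudes are used because over- and under-estimation in different
classes must not cancel in a single national figure; the result is
bounded by the smallest and largest class-bias magnitude.

*Plot-level evaluation.* Predicted AGC is summed over trees whose
centroids fall in each plot polygon; plots without predicted trees are
kept with prediction 0. Reported: per-plot pairs, RMSE, rRMSE =
RMSE/mean(obs) in %, and both bias forms.

*Half-sample ensemble.* k (default 4) CD→DBH fits, each on a seeded
random half of the field table, re-predict every tree's carbon (the
class-specific biomass equation stays fixed, isolating the regression's
contribution). Carbon is summed per (class, hectare cell); the cell-level
spread is sd/mean across the k fits (a cell with mean 0 and sd 0
contributes 0), averaged over cells within each class. This cell-level
definition is recorded in the output metadata since other aggregations
(e.g. pooled RMSE) are conceivable. Seeds are required inputs (defaults
1–4); a degenerate fit in one run is dropped and the number of usable
runs reported. A noiseless field table yields rRMSE identically 0, and
the spread increases with the table's noise level.

## Synthetic data

The scene generator rasterizes lognormal-radius disks/ellipses
(default lognormal(ln 1.0 m, 0.6), keeping most crowns in the 0.25–3 m²
range that dominates real landscapes) onto a grid, placing a
configurable fraction touching an earlier crown (clumps) and the rest
with a ≥2-pixel gap (separable by construction). Later-placed crowns own
contested pixels in the ground truth — an arbitrary but explicit tie
rule; the generator models crown layout, not vertical occlusion. The
field-table generator draws CD lognormally, derives noiseless DBH/AGB
from the calibrated equations, and adds Gaussian (additive, either axis)
or median-preserving lognormal (multiplicative) noise, keeping the
noiseless truth columns for recovery tests. The land-cover generator
places disjoint class rectangles.

What the generators deliberately do **not** emulate: segmentation-model
error characteristics (false positives/negatives, boundary noise,
resolution artefacts), irregular or lobed crown shapes, vertical canopy
structure and understory, spatially correlated allometric residuals, and
real class geometries. Green tests therefore demonstrate correctness of
the algorithms under their stated assumptions, not accuracy on real
imagery — transferring the calibrated equations to a new region still
requires local field data.

## Numerical choices and determinism

- Pixel–centre distances are computed as √(Δrow² + Δcol²) on exact
  integer squares, so the same value is obtained on every code path and
  label assignments are reproducible bit-for-bit.
- All tie-breaks are explicit: smallest centre index in relabelling,
  smallest row-major pixel in plateau merging, first feature in file
  order for boundary points, half-open grid cells.
- Every stochastic procedure takes explicit seeds (`numpy`
  `default_rng`); generators are pure functions of their configuration.
- Fitted-model files store floats via `repr`, which round-trips
  bit-exactly.
- Raster outputs carry GeoTIFF ModelPixelScale/ModelTiepoint tags and a
  JSON image description; writes are byte-stable, which the end-to-end
  determinism test verifies across the whole CLI chain.

## Problem sizes

The test suite and `scripts/acceptance.py` use scenes up to 400 x 400
pixels (one hectare at 0.25 m), 100-scene brute-force comparisons at
48–64 px, 1,000-mask conservation sweeps at 16 px, and 10,000-row field
tables for parameter recovery — sizes at which the brute-force oracles
remain exact references and the full suite runs in well under a minute
of compute on one core. The pipeline itself is tile-based and scales to
arbitrarily many tiles processed independently.

## Known limitations

- The penalty form in relabelling (additive λ·B) is one of several
  defensible choices (multiplicative and geodesic variants exist); it is
  exposed as configuration.
- DCR runs per tile, not per connected component; results are identical
  for λ large because assignments never cross gaps, but differ for small
  λ.
- Canopy cover from the area-mode expansion and from the diameter-mode
  expansion differ by ~13%; the area reading is the default and the
  switch is explicit.
- Below-domain crowns (CD < 0.914 m in linear-model classes) carry zero
  carbon; at 0.25 m resolution this affects crowns of 4–10 pixels, a
  population whose share is scene-dependent.
- The ensemble quantifies only CD→DBH sampling variability, not wood
  density, carbon fraction, or segmentation error.
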