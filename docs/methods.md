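# Methods

`stemscan` benchmarks how well different classes of terrestrial LiDAR
devices recover two basic forest-inventory variables — stem diameter at
breast height (DBH) and tree height (TH) — by simulating the whole chain:
scene, scanner, point cloud, measurement, error statistics.  This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not show.

## Scenes

**Laboratory scene.**  Twelve upright cylindrical tubes on a flat floor
inside a 7 × 7 m area.  The default tube set is the packaged reference
table: diameters 2.6–50.5 cm (mean 17.78 cm, population SD 11.93 cm) and
lengths 100–290 cm (mean 156.58 cm, population SD 70.13 cm).  Tubes are
laid out on a grid with non-overlapping footprints; overlap is rejected.

**Plantation scene.**  A rectangular grid of trees at 4 × 4 m spacing
(the layout of a fast-growing-tree plantation).  Per tree:

- DBH ~ lognormal, mean 25.6 cm, SD 5 cm by default.  The SD is not part
  of the reference description; 5 cm reproduces the spread seen in
  uniform clonal plantations (reference range roughly 17–40 cm).
- TH = a + b·ln(DBH) + ε, the standard allometric form, with slope
  b = 7.5 m per log-unit and the intercept solved so that E[TH] equals
  the target mean of 15.7 m; ε has SD 0.5 m.  The slope reproduces a
  height span of ~11–18 m over the DBH range above.
- Planting scatter: each stem is displaced from its grid node by
  isotropic Gaussian noise with σ = 0.1 m.  Real rows are straight only
  to within a couple of decimetres; perfectly integer-aligned stems also
  create raster-cell boundary artefacts no real site has.

**Tree geometry.**  The stem is a vertical conic frustum with linear
taper: diameter 1.2 × DBH at the ground, exactly DBH at 1.3 m
(taper = 0.2/1.3 relative shrink per metre).  The crown is a cone with
base radius 1.5 m at 60% of tree height and apex at the tree top — the
simplest shape that exposes both a circular breast-height section and a
well-defined apex for the height raster.  Crowns are *porous*: a beam
crosses the crown envelope unreturned with probability 0.5, because the
plantation is scanned in the leaf-off season when crowns are mostly bare
branches.  Porosity matters twice: it lets beams reach stems and apexes
behind other trees, and it thins the crown's own surface returns.

## Device model

A `DeviceProfile` holds point rate, horizontal/vertical field of view,
ranging noise, maximum range, beam pattern, a detection floor (objects
thinner than it return nothing — thin targets vanish for low-resolution
sensors) and a dropout rate.  Four defaults:

| profile | rate (pts/s) | FOV (h × v) | σ range | max range | pattern |
|---|---|---|---|---|---|
| `riegl` | 122 000 | 360° × 100° (−40…+60) | 5 mm | 1400 m | raster lines |
| `stonex` | 976 000 | 360° × 270° | 12 mm | 120 m | uniform |
| `lca_tls` | 240 000 | 70.4° × 77.2° | 20 mm @ 20 m | 190 m | rosette |
| `iphone` | 30 000 | 60° × 45° | 8 mm | 5 m, floor 5 cm | uniform |

Rates, fields of view, the rosette sensor's "2 cm (1σ @ 20 m)" precision
and the phone's 5 m range are manufacturer figures; the remaining σ
values are calibration choices consistent with the device classes.  The
rosette sensor's noise is range-proportional with the 20 m anchor
(σ(r) = 2 cm · r/20 m): at the 3–8 m ranges of plot work its effective
noise is 3–8 mm, which is what its measured cross-section noise bands
imply; a constant 2 cm at all ranges would contradict them.  The tripod
scanner's vertical window is asymmetric about the horizon (−40…+60°),
as panoramic survey scanners are built; `fov_v_offset` expresses this.

**Beam patterns.**

- *Rosette* (non-repetitive): deflection per axis is a sum of two
  cosines with frequency ratio √2; the incommensurate pair never
  retraces, so angular coverage grows with dwell time.  This is a
  qualitative stand-in for prism kinematics, validated only through the
  coverage-monotonicity property.
- *Raster lines*: azimuth sweeps line by line; line elevations follow a
  golden-ratio interleave (lines fill the FOV quasi-uniformly instead of
  retracing frames) and each line's azimuth comb is phase-shifted by a
  plastic-number sequence.  Points per line are set so the azimuth and
  elevation resolutions match, as survey scanners are configured.
- *Uniform*: pseudo-random angles in the FOV window.

**Ray casting.**  Every beam is intersected with the ground plane and
all object frustums; the nearest hit wins, its range is perturbed by
Gaussian noise along the beam, returns beyond the maximum range are
dropped, dropout is Bernoulli.  All randomness derives from a single
seed through `numpy` seed sequences; identical inputs give bit-identical
clouds.

**Scan protocols** (`pipeline.standard_poses`): tripod TLS scans a lab
from its four corners and a plot from a de-aligned 3 × 3 grid of
positions (field crews stand between rows — a scanner on a row line
sights straight down the row and occludes everything behind the first
stem); the narrow-FOV rosette prototype uses twice the positions with
aimed orientations (stem band and upper canopy); the handheld walks the
perimeter plus a pass through the middle; the phone walks along every
row aisle, close to each stem, because of its 5 m range.  Handheld
trajectories carry per-scan rigid registration jitter (5 mm/0.05° for
the SLAM handheld, 15 mm/0.2° for the phone's visual-inertial tracking);
tripod registration is treated as exact.  The pose budget is a total
pulse count split evenly across poses; in benchmarks the per-device
budget scales as point rate × published per-plot collection time
(21 / 4.5 / 13 / 8 minutes), normalised to the tripod TLS.

## DBH chain

1. **Slice**: points with height-above-ground in [1.30, 1.35) m (5 cm
   band; both the band and its centre are configurable because the
   source protocol mentions 2 cm and 5 cm variants), clustered into
   stems by single-linkage at 0.3 m — safe at 4 m spacing.
2. **Circle fit**: Taubin's algebraic fit (SVD form), non-iterative,
   exact on noiseless circles, near-geometric accuracy under small
   noise.
3. **Unwrap**: azimuth about the fitted centre (0–360°) versus radial
   deviation in mm.
4. **Contour model**: least-squares truncated Fourier series (default
   K = 8 harmonics).  A global periodic model has no seam at 0/360°,
   which is why it is preferred over local smoothers.
5. **Noise band**: the central (equal-tail) 2.5–97.5 percentile interval
   of the residuals; its width in mm is the per-section noise figure.
   For Gaussian residuals the width is 3.92σ.  A shortest-interval
   variant is available behind a flag; the equal-tail reading is the
   standard one.
6. **Perimeter**: points are grouped into 72 angular bins about the
   centre (bin phase anchored to the outermost point, which makes the
   estimator exactly covariant under rigid motions); each bin
   contributes its 90th-percentile radius (the outer contour); empty
   bins are filled by periodic interpolation.  The pipeline smooths the
   bin radii with the chain's own truncated Fourier reconstruction
   before building the polygon: raw per-bin quantiles jitter on sparse
   noisy sections and a zig-zag polygon systematically inflates the
   perimeter, which is not what a human smoothly outlining the outer
   contour produces.  DBH = perimeter / π.

The polygon estimator has two known biases, both documented by tests:
a polygon inscribed in a circle is short by the chord factor
(2n·sin(π/n)/2π, −0.03% at 72 bins), and the outer-quantile radius sits
about 1.28 σ_effective outside the true surface under noise, so noisier
devices overestimate DBH — the mechanism behind the device ordering.

## Height chain

DTM = per-cell minimum elevation, DSM = per-cell maximum, nDSM = DSM −
DTM; a tree's height is the nDSM value of the cell containing its stem
position.  Cells are half-open, the origin snaps to a cell-size
multiple, the default cell is 0.5 m (crown scale at 4 m spacing; the
properties hold for 0.25–1 m).  Terrain cells hidden under crowns are
filled from the nearest defined ground cell before subtraction (benign
on a flat site; configurable).  The error of the method on a cone crown
is bounded by the cone slope times the cell diagonal — the worst case
when the best return in the stem cell sits at the cell corner.

Laboratory tube lengths use a different route (tubes have no crown):
two diametrically opposed vertical strips of width 3 cm are cut from the
tube surface and the length is the mean of their vertical extents; one
empty strip falls back to the other, two empty strips mean undetected.

## Error statistics

Error = estimate − reference (positive = overestimation).  RMSE with
divisor n, bias = mean error, rRMSE/rBias as percentages of the
reference mean, R² = squared Pearson correlation, TDR = percentage of
reference objects detected.  Undetected objects are excluded from
RMSE/bias and counted against TDR.  "Variability" in the scene summary
is the population (divisor-n) standard deviation, which is what the
printed reference values use; the sample form is a flag away.

Paired t (n−1 df, two-sided, 95% CI), one-way ANOVA, and — only when
the ANOVA rejects — Tukey's HSD with critical values from the exact
studentized-range distribution (Tukey–Kramer correction for unequal
groups).  The statsmodels implementation is used as an independent
cross-check in the tests; it interpolates tabulated quantiles, which is
why the package computes its own.

## Problem sizes

The synthetic experiments run at deliberately reduced scale: lab surveys
use ~2–3 M pulses, plot surveys ~1–2 M per device (scaled by the
rate × time budgets above), the device-ordering benchmark 20 replicated
3 × 3-tree plots, and height recovery a 4 × 4-tree plot.  Real surveys
collect two orders of magnitude more points; the reduced budgets keep
every property of interest measurable (tens to hundreds of points per
stem section) while a full benchmark finishes in minutes.

## What the synthetic experiments show — and what they do not

Passing tests establish that the measurement chain is internally
correct: geometry is recovered exactly without noise, the noise-band
statistic is calibrated (3.92σ under Gaussian radial noise), height
errors respect the rasterization bound, and the device ordering that
emerges (tripod TLS best, handheld and rosette prototype intermediate,
phone worst) follows from the modelled noise, registration jitter and
range limits alone.  They do not validate the device models against
real hardware: real stems are not circular, real crowns are not cones
with uniform porosity, real SLAM drift is trajectory-correlated rather
than i.i.d. per scan, multi-return and incidence-angle effects are not
modelled, and registration of real multi-scan surveys is never exact.
The laboratory reference tables, by contrast, are real measured data
and are reproduced exactly.

## Numerical choices and degenerate inputs

- Circle fit rejects collinear input (covariance determinant test) and
  non-positive fitted radii.
- The Fourier fit requires ≥ 2K + 1 points; the residual band warns
  below 40 residuals but still computes.
- Percentiles use linear interpolation (`numpy.percentile` default).
- A point exactly at a fitted centre has no azimuth and is an error;
  a point exactly on a raster cell edge belongs to the higher-index
  cell (half-open convention).
- LAS I/O is LAS 1.2, point format 0, 1 mm scale, offset at the floor
  of the bounds: round trips are exact to the 0.5 mm quantum.
- Seeds: one master seed; per-scan and per-replicate seeds are derived
  by `SeedSequence.spawn`, so adding a pose never changes another
  pose's randomness.
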