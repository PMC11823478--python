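# Methods

This note records the model assumptions, constants, numerical choices and
known limitations of the `rownav` pipeline and of the synthetic scene
generator used to validate it.

## Pipeline model and assumptions

The pipeline assumes a forward-looking camera at a declination angle over a
seedling field, so that crop rows appear near-vertical, converge toward a
vanishing point above the frame, and the row to follow lies near the image
center. It further assumes vegetation is separable from soil by excess
green (ExG = 2g − r − b on sum-normalized channels): greenish soils, fallen
leaves and heavy specular highlights degrade the first stage and therefore
everything downstream.

Image coordinates follow the raster convention: origin top-left, x
rightward, y downward. Lines are parameterized axis-swapped, `x = a·y + b`,
because the target rows are near-vertical; the reported angle is taken
against the image-bottom horizontal and lies in (0°, 180°), with 90° a
perfectly vertical row.

## Constants

| Constant | Default | Meaning |
|---|---|---|
| `k_otsu` | 0.8 | fraction of the Otsu threshold used for binarization |
| morphology schedules | piecewise in NZPR | erosion iterations per resolution; dilations = ⌊erosions/2⌋; none below 6 % NZPR; 3×3 kernel |
| `c_area` | 0.7 | component kept iff area ≥ 0.7 × mean component area |
| `roi_frac` | 0.35 | central column fraction searched for the baseline |
| `reduce_window` | 8×8 px | pixel-reduction window before clustering |
| `eps`, `min_pts` | 200 px, 4 | DBSCAN radius and core-point threshold |
| `cod0`, `cod_step` | 0.65, 0.05 | centroid-distance sweep for centerline candidates |
| trapezoid | 0.07·W top width, slope 1/12 | confirmation ROI, baseline as median |
| `sigmoid_k`, `sigmoid_x0` | −8.67, 0.354 | NZPR→threshold map for the fitting region |
| `cut_coeff` | 1.2 | projection cut level `(1.2 − t)·y_max` |
| `feature_window` | 16×32 px | feature-point window before fitting |
| RANSAC | t = 0.155 (width-normalized), CL = 0.99, n = 2, cap 10 000 | consensus fitting |

NZPR enters every formula as a fraction in [0, 1] even though it is usually
quoted as a percentage; the >50 % branch of the 640×480 schedule is
consistent with its quadratic only under that convention (the quadratic
evaluates to 4.70 at 0.5, rounding to the branch constant 5).

## Numerical choices

- **Rounding** in the morphology schedules is half-away-from-zero, the
  conventional reading of round(·); the 1920×1080 quadratic passes very
  close to 0.5 at NZPR = 0.06, so the convention is load-bearing.
- The 1920×1080 schedule's two upper branches disagree at NZPR = 0.50
  (7 vs. 8); the branches are implemented literally, not smoothed.
- **Otsu ties** go to the smallest maximizing threshold; a constant image
  returns its single level with a warning.
- **Baseline ties** go to the column nearest W/2, then the smaller column.
  An all-background ROI raises a typed no-vegetation error: every later
  stage assumes a crop row exists.
- **Boundary convention** for the trapezoid cross products: a point exactly
  on an oblique line counts as inside.
- The **fitting region** is the contiguous super-threshold column run
  containing the baseline; if the baseline column itself falls below the
  cut the run containing the projection maximum is used instead. An
  `outermost` mode (first to last super-threshold column) is available in
  the config.
- **RANSAC distance threshold units**: 0.155 is implausibly small for raw
  pixel residuals of window-mean points, so by default coordinates are
  normalized by image width before fitting and the threshold applies there;
  a raw-pixel mode is exposed (`ransac_normalized: false`). With the
  default at 640 px width the effective radius is ≈ 99 px, so RANSAC acts
  as a gross-outlier guard and the least-squares refit does the precision
  work — consistent with fitting an already heavily cleaned mask.
- **Least squares** is solved as x on y; exactly horizontal inlier sets
  (impossible for real rows) raise a typed degeneracy error rather than
  returning an unrepresentable line.
- **DBSCAN determinism**: seeds are processed in raster point order and
  clusters expanded breadth-first over sorted neighbor lists, so a border
  point reachable from two clusters is always claimed by the same one.
  Neighbor queries go through a KD-tree; the partition is bit-identical to
  a naive O(n²) implementation under the same ordering.
- `eps = 200` px is kept as the published default at both resolutions. At
  640×480 it can bridge adjacent rows into one cluster when inter-row
  spacing dips below it; the fitting-region cut still isolates the central
  row in that case. A width-proportional mode (`eps·W/1920`) is exposed.
- The NZPR driving the sigmoid threshold is recomputed on the centerline
  mask, not the whole frame: the map's operating points correspond to
  median-row densities.

## Synthetic scenes

`rownav.synthfield` renders what the pipeline needs to see, not
photorealism: textured soil, rows of leaf-rosette plants converging to a
vanishing point, off-row weeds, optional seedling-absence gaps, and
low-light / rain degradations. Defaults (640×480, 3 rows, 260 px row
spacing at the bottom of the frame, vanishing point 2 500 px above the top,
plants every 35 px along the row, leaves 12–26 px, 3 weeds at least 60 px
off-row) were chosen once to mimic a seedling-stage field shot at a ~45°
declination: rows that look continuous, stay separable at the published
eps, and occupy a few percent NZPR. Gap scenes remove a 260 px span of the
center row, enough to split it into two DBSCAN clusters and exercise the
multi-cluster centerline path.

Deliberate simplifications, and what they mean for test evidence:

- Soil colors are constructed strictly non-green (excess-green deficit
  ≥ 24 at full albedo, albedo blotches multiplicative, grain
  luminance-correlated), so ExG maps soil to exactly zero. Real soil has a
  faint positive ExG tail; the Otsu threshold therefore does real work in
  the field but is nearly trivial on clean synthetic scenes. Passing
  recovery tests demonstrate the geometry pipeline, not ExG robustness on
  difficult soils.
- Leaves are flat ellipses without occlusion ordering, specularity or
  shadows; rain is a streak overlay, not refraction.
- Perspective is linear convergence only — no lens distortion, no terrain
  relief.
- Scenes are single-frame; there is no temporal smoothing to test.

All randomness comes from one `numpy` generator seeded per scene, so a
spec + seed pair reproduces the image bit for bit.

## Evaluation

Yaw angles are folded to [0°, 90°] via |cos| because line directions are
sign-ambiguous. MEA ≤ RMSE holds by Jensen's inequality and is asserted in
tests. MRE divides by the annotated angle against the bottom horizontal;
records with a zero annotated angle are excluded with a warning rather
than propagating a division by zero. Synthetic-recovery checks use 50
clean scenes with center-row angles spread over 80°–100° and 20 gap
scenes; these sizes keep the whole suite fast while leaving the aggregate
statistics stable across seeds.

## Known limitations

- One near-vertical central row is assumed: no curved rows, no
  multi-row output, no lateral-offset (cross-track) metric.
- A frame whose central 35 % of columns contains no vegetation aborts with
  `no_vegetation` by design.
- Heavily textured green weeds directly on the center row can inflate the
  fitting region; the generator places weeds off-row, so this failure mode
  is not covered by the synthetic suite.
- The trapezoid ROI dimensions are one reading of an under-specified
  geometry (full-height oblique lines, top width 0.07·W, slope 1/12,
  widening downward); all four anchors are configurable.
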