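# rownav

Navigation-line extraction for crop seedling rows in RGB field imagery.

Agricultural robots steering between seedling rows (sugarcane, corn, rice)
need a single straight reference line along the central crop row of each
camera frame. `rownav` implements a classical, pixel-wise image-processing
pipeline for that task — no learned models, no GPU — together with a seeded
synthetic field-scene generator so every stage can be tested with exact
ground truth and no field data.

## The algorithm

Given a frame resized to 640×480 or 1920×1080:

1. **Excess-green grayscale.** With (r, g, b) the RGB channels normalized by
   their sum, each pixel maps to `255·clip(2g − r − b, 0, 1)` — vegetation
   bright, soil dark.
2. **Scaled Otsu binarization.** Otsu's threshold t\* maximizes the
   between-class variance σ²_B(t); the mask keeps pixels with
   `gray > k·t\*`, k = 0.8.
3. **NZPR-adaptive opening.** The non-zero pixel ratio
   (NZPR = foreground fraction) proxies canopy density. Erosion iteration
   counts follow piecewise polynomial schedules in NZPR (separate models per
   resolution, 3×3 kernel, dilations = ⌊erosions/2⌋, none below 6 %).
4. **Component filtering + baseline.** 8-connected components smaller than
   0.7× the mean component area are dropped; the *baseline* is the column
   with the maximum foreground count inside the central 35 % of columns.
5. **Reduction + clustering.** Non-overlapping 8×8 windows are reduced to
   their foreground-mean points; DBSCAN (eps = 200 px, minPts = 4) with
   KD-tree neighbor queries groups them into plantation-row clusters.
6. **Centerline selection.** Clusters with centroid distance
   `dᵢ ≤ cod·d̄` from the baseline (cod sweeps 0.65, 0.70, …) are confirmed
   by an isosceles trapezoidal ROI (baseline as median, top width 0.07·W,
   side slope |dx/dy| = 1/12) via signed cross products. Several clusters may
   jointly form the centerline — that is what bridges seedling-absence gaps.
7. **Sigmoid fitting region.** With t = 1/(1 + e^(−k(NZPR − x₀))),
   k = −8.67, x₀ = 0.354 evaluated on the centerline mask, the column
   projection is cut at `(1.2 − t)·y_max`; the super-threshold interval
   containing the baseline is the fitting region.
8. **RANSAC + least squares.** 16×32-window feature points are fitted by
   seeded RANSAC (distance threshold 0.155 in width-normalized coordinates,
   confidence 0.99, iterations `k = ⌈log(1−CL)/log(1−p²)⌉`) and refined by
   least squares over the inliers, regressing x on y (rows are
   near-vertical).

Accuracy against reference lines is scored by the yaw angle
α = arccos(|v₁·v₂| / (‖v₁‖‖v₂‖)) and its aggregates MEA (mean), RMSE, and
MRE (relative to the annotated angle vs. the image-bottom horizontal).

## Worked example

```python
from rownav import PipelineConfig, run_pipeline
from rownav.evaluate import aggregate_metrics, make_record
from rownav.synthfield import SceneSpec, generate_scene

img, ann = generate_scene(SceneSpec(center_angle_deg=86.0, seed=7))
result = run_pipeline(img, PipelineConfig())
print(result.status)                      # ok
print(round(result.line.angle_deg, 2))    # 88.03
rec = make_record(ann.image_id, result.line, ann)
print(round(rec.yaw_deg, 2))              # 2.03
print(result.diagnostics["baseline_column"],
      result.diagnostics["fitting_interval"])   # 333 [320, 354]
```

The scene's ground-truth center row is inclined 86.0° from the bottom
horizontal; the pipeline finds the baseline at column 333, cuts the fitting
region to columns 320–354 (sigmoid t ≈ 0.94 at centerline NZPR ≈ 3.8 %),
and fits a line at 88.03° — a yaw error of 2.03°. Over 50 seeded clean
scenes spanning 80°–100° the package reports MEA ≈ 2.3°, MRE ≈ 2.6 %
(see `tests/test_acceptance.py`).

The same pipeline is available from the shell:

```bash
rownav synth --n 5 --seed 0 --out-dir scenes/          # scenes + ground truth
rownav process --input scenes/ --json out/ --overlay out/
rownav eval --predictions out/ --annotations scenes/annotations.jsonl
```

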