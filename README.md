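# pcmfiber

Fiber counting in phase-contrast microscope (PCM) images: segmentation
post-processing, rotated-rectangle morphometry, regulatory counting
criteria, IoU-matched evaluation against expert annotations, and airborne
fiber-concentration estimation — with a synthetic PCM field simulator that
provides pixel-exact ground truth.

## Who this is for

Regulatory monitoring of airborne asbestos (e.g. around building demolition
sites) counts fibers on membrane-filter samples under a phase-contrast
microscope at 400×. An analyst inspects circular fields of view 300 µm in
diameter and counts every fiber satisfying the countable-fiber definition;
counts per field scale to a concentration in fibers per liter of sampled
air. Segmentation models (semantic or instance) can automate the detection
step, but everything downstream of the raw model output — turning pixels
into calibrated lengths and widths, applying the counting rules, scoring
detections against an expert, and converting counts to a concentration —
is generic image analysis that this package implements and tests.

## The method

**Countable fiber.** With length *L*, width *W* (µm) and aspect ratio
*L*/*W*, a fiber is counted iff

```
L ≥ 5 µm   and   W < 3 µm   and   L/W ≥ 3
```

(the length and aspect bounds inclusive, the width bound strict).

**Morphometry.** A detected fiber is an explicit pixel group. Its rotated
minimum-area bounding rectangle (sides in pixel-count units: center span +
1 px) gives the length as the long side. Width is measured two ways,
mirroring the two segmentation-output styles:

- *instance style*: the orthogonal pixel count at the rectangle center;
- *semantic style*: the mean orthogonal pixel count over all populated
  sections along the long axis.

Pixels convert to microns by the calibration scale (default 0.3125 µm/px,
i.e. 10 µm ≡ 32 px).

**Evaluation.** Predictions match expert polygons one-to-one, greedily by
descending IoU, at IoU ≥ 0.5. Matched = true positive, unmatched truth =
overlooked (FN), unmatched prediction = overcounted (FP), and

```
recall = TP / (TP + FN)        precision = TP / (TP + FP)
```

**Concentration.** With mean countable fibers per field n̄, effective
filter diameter D (35 mm for a 47-mm filter), field diameter d (300 µm) and
sampled air volume V (L):

```
C [fibers/L] = n̄ · (D/d)² / V
```

At n̄ = 5.5, V = 2400 L this gives 31.2 fibers/L.

## Worked example

Simulate three high-contrast fields and run the full pipeline (classical
detector → morphometry → criteria → evaluation → concentration):

```sh
pcmfiber simulate --easy --n-scenes 3 --seed 42 --out fields/
pcmfiber run --in fields/ --out results/
```

prints

```json
{
  "n_images": 3,
  "mean_fibers_per_field": 4.666666666666667,
  "fibers_per_L_rounded": 26.5,
  "recall_percent": 100,
  "precision_percent": 100
}
```

Every detected object in every field was measured (`results/measurements.csv`):

```
image,id,convention,length_um,width_um,aspect_ratio,meets_criteria,fallback
scene-000,0,semantic_style,11.265042040329716,1.0243055555555556,10.997735958016808,True,False
scene-000,1,semantic_style,1.5625,1.3125,1.1904761904761905,False,False
scene-000,2,semantic_style,26.425601211423526,1.441176470588235,18.33613145282449,True,False
```

Row 1 is a countable fiber 11.3 µm long and 1.0 µm wide; row 2 is a
non-fiber particle (aspect 1.2 < 3) that the criteria correctly reject.
`results/report.csv` holds the per-field bookkeeping against the simulated
ground truth:

```
image,expert_count,counted,overlooked,overcounted
scene-000,8,8,0,0
scene-001,2,2,0,0
scene-002,4,4,0,0
Total,14,14,0,0
```

All 14 countable fibers were found with no overcounts, hence 100 % recall
and precision. (The concentration line uses the default 300-µm sampling
geometry; pass a config with a matching `sampling` block when your fields
differ.)

The same workflow is available as library calls
(`generate_scene`, `classical_detect`, `semantic_postprocess`,
`measure_semantic_style`, `apply_criteria`, `match_detections`,
`concentration_fibers_per_L`) — see the docstrings and `docs/methods.md`.

## File dialects

- **Annotations**: LabelMe polygon JSON (`imagePath`, `imageHeight`,
  `imageWidth`, `shapes[].points`/`label`/`description`), labels mapped
  onto `countable_fiber` / `subcriteria_fiber`.
- **Images**: JPEG/PNG, RGB converted to grayscale by the BT.601 luma rule.
- **Model outputs**: probability maps as `.npy` arrays in [0, 1]; instance
  detections as class probability + soft mask (`pcmfiber.backends`).
- **Reports**: CSV (per-image rows + `Total`) and JSON with TP/FN/FP,
  recall and precision.

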