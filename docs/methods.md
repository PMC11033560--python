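# Methods

This note documents the models, conventions and numerical choices behind
`pcmfiber`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic validation does and does not
demonstrate.

## Coordinate and rasterization conventions

Pixels are 0-based, `x` = column, `y` = row; the center of pixel
`(row, col)` sits at continuous coordinates `(col, row)`, so a `W × H`
raster spans `[-0.5, W-0.5] × [-0.5, H-0.5]`. Polygon vertices live in this
continuous space. Rasterization keeps every pixel whose center lies inside
or on the polygon boundary (boundary-inclusive, verified against a
crossing-number oracle); overlapping polygons are drawn in order with the
later shape winning. RGB images collapse to grayscale by the fixed BT.601
luma rule (0.299 R + 0.587 G + 0.114 B, rounded).

## Segmentation post-processing

Two output contracts cover the common segmentation families:

- **semantic**: one probability map; fiber pixels are those with
  probability *strictly greater* than 0.5, grouped into connected
  components. Connectivity defaults to 8 so diagonal fiber runs stay
  connected; 4 is available. No minimum-size suppression is applied by
  default (`min_pixels=1`).
- **instance**: per-object class probability and soft mask; objects with
  class probability *strictly greater* than 0.5 are kept, and pixels with
  mask value *greater than or equal to* 0.8 form the fiber. The asymmetric
  strictness (strict class cut, inclusive mask cut) is deliberate and
  matches the counting convention this package implements; both thresholds
  are parameters.

The **classical detector** exists so the pipeline runs end to end without a
trained network; it is an engineering component, not a claim about any
particular model. Chain: normalize to [0, 1] → background = median grey →
darkness = clip(background − image, 0) → Gaussian smooth (σ = 0.7 px) →
logistic map centered at 0.4 × the 99.9th-percentile darkness with softness
12.5 % of that level. A field whose robust peak darkness is below 0.08 is
declared empty (guards blank fields against thresholding pure noise). The
0.4 relative level places the detection boundary slightly outside the
half-depth contour of a fiber's intensity profile, so detected strokes are
marginally wider than truth (≲ 1 px per side) — conservative for IoU
matching. Deterministic for fixed parameters.

## Morphometry

Both conventions start from the rotated minimum-area rectangle over pixel
centers, computed by rotating calipers on the convex hull, minimizing the
pixel-count area `(span_u + 1)(span_v + 1)`. The `+1` (half-pixel margin at
each end) makes side lengths count pixels: a solid 16-px bar measures
exactly 16 px = 5.0 µm at 0.3125 µm/px, which is the minimum countable
length. The long-side angle is normalized to [0°, 180°).

Width measurement bins pixel centers into unit-width sections along the
long axis (bin k = pixels whose long-axis offset rounds to k):

- *instance style* takes the mean of the populated sections within one
  section of the center. A single center section aliases badly on diagonal
  orientations (at 45° lattice cross-sections alternate sparse/dense), and
  the 3-section neighborhood suppresses this while staying exact on
  constant-width bars. If the whole neighborhood is empty (C-shaped
  fibers whose rectangle center lies outside the stroke), the nearest
  populated section is used and the measurement is flagged `fallback`.
- *semantic style* averages the orthogonal count over *all* populated
  sections. Empty sections are excluded from the mean: including them would
  drag the width of curved fibers toward zero.

"Center point" means the rectangle center (not the pixel centroid).
Measured length and width are not forced into an ordering — a strongly
curved fiber can measure wider than long — but
`aspect_ratio × width_um = length_um` holds to machine precision by
construction.

Rotation equivariance (length and width within ±1 px across 0°/30°/45°/90°)
and agreement with a dense-angle caliper brute force (area within 1 % on
random blobs) are enforced by tests.

## Counting criteria and concentration

The countable-fiber rule is `L ≥ 5 µm ∧ W < 3 µm ∧ L/W ≥ 3`, with the
printed inclusivities exactly (length and aspect inclusive, width strict);
boundary behavior is property-tested, and the rule is monotone (longer
never disqualifies, wider never qualifies).

Concentration: `C = n̄ (D/d)² / V` with n̄ the mean countable count per
field, D the effective filter diameter, d the field diameter, V the air
volume. Defaults: D = 35 mm — the standard effective diameter of a 47-mm
membrane filter in its holder — d = 300 µm, V = 2400 L, under which
n̄ = 5.5 gives 31.2 fibers/L. Reported concentrations round half-up to one
decimal. No blank correction or Poisson interval is computed.

## Evaluation

IoU defaults to the standard union form `|A∩B| / |A∪B|`; a literal
sum-denominator variant `|A∩B| / (|A|+|B|)` is kept as `mode="sum"`
because counting protocols sometimes state that formula while naming IoU
(note `sum` of two identical sets is 0.5, so the 0.5 threshold is only
meaningful in union mode). Matching is greedy one-to-one in descending IoU
(ties: smaller prediction index, then smaller truth index); an exhaustive
`strategy="optimal"` exists for audit. With disjoint ground-truth masks and
threshold ≥ 0.5, each prediction can qualify against at most one truth, so
greedy and optimal coincide — verified exhaustively on randomized small
instances. Recall/precision are micro-averaged from pooled TP/FN/FP and
reported as integer percentages, rounded half-up. By default only
criteria-passing predictions are matched against criteria-passing truths;
`include_subcriteria=True` matches everything (diagnostic).

## Synthetic PCM fields

The simulator emulates filter preparations viewed in phase contrast: a
circular field of view (default 300 µm across at 0.3125 µm/px in a
1600 × 1200 raster) with fibers, compact particles, and Gaussian camera
noise. A fiber is a centerline stroked at its true width: straight for
amosite-like fibers, perpendicular-sinusoid perturbed (amplitude =
`waviness` × chord, 1–2.5 periods) for chrysotile-like ones. The curve is
similarity-rescaled so its **arc length equals the sampled length exactly**,
and the stroke is trimmed by half a width at each end so the rendered
butt-ended capsule's tip-to-tip extent equals the true length — this is
what makes rectangle morphometry on the truth mask recover length and width
to ±1 px. Appearance: intensity dip `depth · 2^{−(2r/W)²}` (half depth at
the true edge r = W/2) plus a bright halo ring just outside the stroke;
both invented, parameterized in `SceneSpec`. The area outside the disc is a
constant grey equal to the background level.

Defaults define the study conditions: fiber count ~ Poisson(5.5 · 37/35),
chosen analytically so the expected *countable* count is 5.5 per field
under lengths U(3, 40) µm (countable fraction 35/37; widths U(0.3, 1.5) µm
keep the width and aspect criteria non-binding). Ground-truth countability
applies the criteria to the true arc length and width; annotation polygons
are the traced outlines of the rendered core masks, labeled
countable/sub-criteria accordingly. Scenes are bit-reproducible from
(spec, seed). `scene_to_density` estimates the countable density on
noise-free, particle-free renders of the same fiber process (counts are
unaffected; the render is cheaper).

The `easy_scene_spec` preset (512² raster, 150-µm field, straight fibers
8–30 µm × 0.8–1.5 µm, low noise, ≥ 6 px footprint separation) defines the
"easy regime" for end-to-end validation: high contrast, no overlap, no
near-boundary dimensions. Problem sizes throughout the validation suite
(300–512 px rasters, tens to low hundreds of scenes) were chosen as the
smallest that leave the Monte-Carlo checks well inside their 3-SE bands.

**What passing does and does not show.** The simulator has no defocus,
no fiber bundles or entanglement, no filter texture, no uneven
illumination, and particles are simple blobs; 100 % end-to-end accuracy in
the easy regime demonstrates that the post-processing, morphometry,
counting and evaluation stages are correct and consistent — not that the
classical detector (or any model) would reach that accuracy on real
micrographs, where contrast, clutter and overlap dominate.

## Known limitations

- Length is the rectangle long side, not arc length, so the measured
  length of a wavy fiber underestimates its true arc length; a strongly
  curved countable fiber can be measured as sub-criteria. This is a
  property of the rectangle convention itself, preserved deliberately.
- Field-edge counting rules (fibers crossing the graticule boundary) and
  split/bundle rules are not implemented; the simulator places fibers
  wholly inside the disc.
- No asbestos-type discrimination: PCM counts fibers, not asbestos
  specifically.
- Timing/throughput is out of scope.
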