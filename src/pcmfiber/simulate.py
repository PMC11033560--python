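"""Synthetic phase-contrast field-of-view generator with pixel-exact truth.

Emulates micrographs of membrane-filter preparations observed through a
counting graticule: a circular field of view (default 300 um across at
0.3125 um/px) containing straight, rigid fibers (amosite-like) and/or wavy
thin fibers (chrysotile-like), plus compact non-fiber particles and camera
noise.  Appearance follows the phase-contrast signature of a transparent
fiber: a dark core with a Gaussian cross-section and a bright halo ring.

Every scene is a pure function of (SceneSpec, seed): the rendered image
bytes, the ground-truth fiber list and the annotation polygons are
bit-identical across runs.  The area outside the field disc is rendered at
the same constant grey as the interior background level (documented
constant, no noise), so the field boundary introduces no artificial
contrast edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure as skmeasure

from .counting import CountingCriteria, meets_criteria
from .io import COUNTABLE, SUBCRITERIA, AnnotationSet, CalibratedImage, Shape

#: Default fiber-count rate: Poisson mean chosen so the expected *countable*
#: count is 5.5 per field under the default U(3, 40) um length distribution,
#: whose countable fraction is 35/37 (widths <= 1.5 um make the width and
#: aspect criteria non-binding).
_DEFAULT_FIBER_RATE = 5.5 * 37.0 / 35.0


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for one synthetic field of view.

    Distributions are tuples: ``("uniform", lo, hi)``, ``("normal", mu, sd)``
    (truncated at 0), ``("lognormal", mu, sigma)`` or ``("fixed", v)``.
    Counts may be a plain integer or ``("poisson", rate)``.

    waviness is the perpendicular sinusoidal amplitude as a fraction of the
    centerline chord: 0 gives straight amosite-like fibers, ~0.05-0.15 wavy
    chrysotile-like ones.  min_separation_px > 0 rejection-samples object
    positions so rendered footprints keep at least that gap (used by the
    "easy" preset to avoid overlapping fibers).
    """

    field_diameter_um: float = 300.0
    image_size_px: tuple[int, int] = (1600, 1200)  # (width, height)
    scale_um_per_px: float = 0.3125
    n_fibers: int | tuple = ("poisson", _DEFAULT_FIBER_RATE)
    length_um_dist: tuple = ("uniform", 3.0, 40.0)
    width_um_dist: tuple = ("uniform", 0.3, 1.5)
    waviness: float = 0.05
    n_particles: int | tuple = ("poisson", 3.0)
    particle_size_dist: tuple = ("uniform", 0.5, 2.5)  # diameter, um
    noise_sd: float = 0.02
    halo_strength: float = 0.12
    background: float = 0.72
    core_depth: float = 0.4
    min_separation_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_diameter_um <= 0 or self.scale_um_per_px <= 0:
            raise ValueError("field diameter and scale must be positive")
        if self.waviness < 0 or self.noise_sd < 0 or self.halo_strength < 0:
            raise ValueError("waviness, noise_sd and halo_strength must be >= 0")
        w, h = self.image_size_px
        if self.field_diameter_um / self.scale_um_per_px > min(w, h):
            raise ValueError("field disc does not fit inside the image raster")

    @property
    def field_radius_px(self) -> float:
        return self.field_diameter_um / self.scale_um_per_px / 2.0


@dataclass
class GroundTruthFiber:
    """True geometry of one rendered fiber.

    ``true_length_um`` is the arc length of the centerline; ``is_countable``
    applies the counting criteria to the true dimensions.  ``pixels`` is the
    exact rendered core mask as (row, col) indices.
    """

    centerline: np.ndarray
    true_length_um: float
    true_width_um: float
    is_countable: bool
    pixels: np.ndarray = field(repr=False, default=None)


def easy_scene_spec(
    image_size_px: tuple[int, int] = (512, 512),
    field_diameter_um: float = 150.0,
    n_fibers: int | tuple = ("poisson", 5.5),
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SceneSpec:
    """High-contrast, well-separated preset for desk-scale end-to-end runs:
    straight fibers comfortably inside the countable range, low noise, and a
    minimum footprint separation so objects never merge."""
    return SceneSpec(
        field_diameter_um=field_diameter_um,
        image_size_px=image_size_px,
        n_fibers=n_fibers,
        length_um_dist=("uniform", 8.0, 30.0),
        width_um_dist=("uniform", 0.8, 1.5),
        waviness=0.0,
        n_particles=("poisson", 2.0),
        particle_size_dist=("uniform", 0.6, 2.0),
        noise_sd=noise_sd,
        halo_strength=0.08,
        core_depth=0.45,
        min_separation_px=6.0,
        seed=seed,
    )


def _sample_dist(rng: np.random.Generator, dist) -> float:
    if isinstance(dist, (int, float)):
        return float(dist)
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "normal":
        return float(max(rng.normal(dist[1], dist[2]), 1e-6))
    if kind == "lognormal":
        return float(rng.lognormal(dist[1], dist[2]))
    raise ValueError(f"unknown distribution {dist!r}")


def _sample_count(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, (int, np.integer)):
        if spec < 0:
            raise ValueError("count must be >= 0")
        return int(spec)
    if isinstance(spec, tuple) and spec[0] == "poisson":
        return int(rng.poisson(spec[1]))
    return int(round(_sample_dist(rng, spec)))


def dist_mean(dist) -> float:
    """Analytic mean of a distribution tuple (for Monte-Carlo checks)."""
    if isinstance(dist, (int, float)):
        return float(dist)
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        return (dist[1] + dist[2]) / 2.0
    if kind in ("normal", "poisson"):
        return float(dist[1])
    if kind == "lognormal":
        return math.exp(dist[1] + dist[2] ** 2 / 2.0)
    raise ValueError(f"unknown distribution {dist!r}")


def _centerline(rng, length_px, waviness, center, direction_rad, n_min=8):
    """Sampled centerline with arc length exactly length_px, centered at
    ``center``.  Waviness adds a perpendicular sinusoidal displacement of
    amplitude waviness*chord; the curve is similarity-rescaled so its arc
    length equals the requested length."""
    n = max(n_min, int(2 * length_px))
    t = np.linspace(0.0, 1.0, n)
    dx, dy = math.cos(direction_rad), math.sin(direction_rad)
    chord = length_px
    base = np.column_stack([(t - 0.5) * chord * dx, (t - 0.5) * chord * dy])
    if waviness > 0:
        periods = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        amp = waviness * chord
        off = amp * np.sin(2.0 * math.pi * periods * t + phase)
        base += np.column_stack([-dy * off, dx * off])
    arc = float(np.sum(np.linalg.norm(np.diff(base, axis=0), axis=1)))
    pts = base * (length_px / arc)  # similarity rescale: arc becomes exact
    return pts + np.asarray(center)


def _trim_for_caps(pts, width_px):
    """Shorten a sampled centerline by width/2 of arc length at each end, so
    that stroking it with round caps of radius width/2 yields a capsule whose
    tip-to-tip extent equals the original arc length (butt-ended fiber)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    half = width_px / 2.0
    if total <= 2.0 * half + 1e-9:
        mid = int(np.searchsorted(s, total / 2.0))
        return pts[mid : mid + 1]
    lo, hi = half, total - half
    inner = pts[(s > lo) & (s < hi)]
    ends = [np.array([np.interp(v, s, pts[:, 0]), np.interp(v, s, pts[:, 1])]) for v in (lo, hi)]
    return np.vstack([ends[0], inner, ends[1]])


def _stamp(img, occupancy, pts_xy, width_px, spec, record_mask):
    """Render one object (fiber centerline or particle point set) into the
    image.  Returns (accepted, mask_coords): accepted is False when the
    min-separation occupancy test fails; mask_coords are the core (row, col)
    pixels when record_mask is set."""
    h, w = img.shape
    halo_center = width_px / 2.0 + 1.5
    pad = int(math.ceil(width_px / 2.0 + halo_center + 5.0))
    c0 = max(int(math.floor(pts_xy[:, 0].min())) - pad, 0)
    c1 = min(int(math.ceil(pts_xy[:, 0].max())) + pad, w - 1)
    r0 = max(int(math.floor(pts_xy[:, 1].min())) - pad, 0)
    r1 = min(int(math.ceil(pts_xy[:, 1].max())) + pad, h - 1)
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    grid = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    d = cdist(grid, pts_xy).min(axis=1).reshape(rows.shape)

    if spec.min_separation_px > 0:
        dilated = d <= width_px / 2.0 + spec.min_separation_px / 2.0
        if np.any(occupancy[r0 : r1 + 1, c0 : c1 + 1] & dilated):
            return False, None
        occupancy[r0 : r1 + 1, c0 : c1 + 1] |= dilated

    dip = spec.core_depth * np.exp2(-np.square(2.0 * d / width_px))
    dip[d > 1.5 * width_px] = 0.0
    halo = spec.halo_strength * np.exp(-np.square((d - halo_center) / 1.2))
    img[r0 : r1 + 1, c0 : c1 + 1] += halo - dip

    mask_coords = None
    if record_mask:
        mask = d <= width_px / 2.0
        mask_coords = np.argwhere(mask) + np.array([r0, c0])
        if mask_coords.size == 0:  # sub-pixel-wide stroke: keep nearest pixel
            rr, cc = np.unravel_index(np.argmin(d), d.shape)
            mask_coords = np.array([[rr + r0, cc + c0]])
    return True, mask_coords


def _mask_polygon(mask_coords, image_size):
    """Contour polygon (x, y vertices) around a core pixel mask."""
    r0, c0 = mask_coords.min(axis=0)
    r1, c1 = mask_coords.max(axis=0)
    local = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=float)
    local[mask_coords[:, 0] - r0 + 1, mask_coords[:, 1] - c0 + 1] = 1.0
    contours = skmeasure.find_contours(local, 0.5)
    contour = max(contours, key=len)
    xy = np.column_stack([contour[:, 1] + c0 - 1, contour[:, 0] + r0 - 1])
    xy = xy[:: max(1, len(xy) // 80)]
    if len(xy) < 3:
        rr, cc = mask_coords[0]
        xy = np.array([[cc - 0.4, rr - 0.4], [cc + 0.4, rr - 0.4], [cc, rr + 0.4]], float)
    w, h = image_size
    xy[:, 0] = np.clip(xy[:, 0], -0.5, w - 0.5)
    xy[:, 1] = np.clip(xy[:, 1], -0.5, h - 0.5)
    return xy


def render_fiber_mask(
    length_px: float,
    width_px: float,
    angle_deg: float,
    waviness: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Rasterize a single fiber stroke at a controlled orientation.

    Returns the core-mask pixels as an (n, 2) array of (row, col).  This is
    the same stroke geometry the scene generator renders (butt-ended capsule
    of tip-to-tip extent ``length_px``), exposed for validation: measuring
    the returned mask should recover length_px and width_px to ~1 px at any
    orientation.
    """
    rng = np.random.default_rng(seed)
    pad = length_px + width_px + 6.0
    # generic sub-pixel offset: keeps capsule tips off exact pixel centers,
    # where the boundary-inclusive fill would count one extra pixel
    pts = _centerline(rng, length_px, waviness, (pad + 0.3, pad + 0.2), math.radians(angle_deg))
    pts = _trim_for_caps(pts, width_px)
    span = int(math.ceil(2 * pad))
    cols, rows = np.meshgrid(np.arange(span), np.arange(span))
    grid = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    d = cdist(grid, pts).min(axis=1).reshape(rows.shape)
    coords = np.argwhere(d <= width_px / 2.0)
    if coords.size == 0:
        rr, cc = np.unravel_index(np.argmin(d), d.shape)
        coords = np.array([[rr, cc]])
    return coords


def generate_scene(
    spec: SceneSpec,
    seed: int | None = None,
    criteria: CountingCriteria = CountingCriteria(),
    field_id: str | None = None,
) -> tuple[CalibratedImage, list[GroundTruthFiber], AnnotationSet]:
    """Render one synthetic field of view.

    Returns the calibrated image, the ground-truth fiber list and a LabelMe-
    style AnnotationSet whose shapes are the fiber core outlines, labeled
    countable/sub-criteria from the true dimensions.  Raises RuntimeError
    when a fiber cannot be placed inside the field disc within the bounded
    retry budget.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if field_id is None:
        field_id = f"sim-{seed:05d}"

    width, height = spec.image_size_px
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    R = spec.field_radius_px

    img = np.full((height, width), spec.background, dtype=float)
    occupancy = np.zeros((height, width), dtype=bool)

    n_fibers = _sample_count(rng, spec.n_fibers)
    n_particles = _sample_count(rng, spec.n_particles)

    fibers: list[GroundTruthFiber] = []
    for _ in range(n_fibers):
        # sample dimensions; a fiber longer than the field is resampled
        for attempt in range(100):
            length_um = _sample_dist(rng, spec.length_um_dist)
            if length_um < spec.field_diameter_um - 2.0 * spec.scale_um_per_px:
                break
        else:
            raise RuntimeError("could not sample a fiber shorter than the field diameter")
        for _ in range(100):
            width_um = _sample_dist(rng, spec.width_um_dist)
            if width_um < length_um:
                break
        length_px = length_um / spec.scale_um_per_px
        width_px = max(width_um / spec.scale_um_per_px, 1.0)

        placed = False
        clearance = R - (width_px / 2.0 + 2.0)
        for _ in range(80):
            direction = rng.uniform(0.0, math.pi)
            rad = clearance * math.sqrt(rng.uniform(0.0, 1.0))
            ang = rng.uniform(0.0, 2.0 * math.pi)
            center = (cx + rad * math.cos(ang), cy + rad * math.sin(ang))
            pts = _centerline(rng, length_px, spec.waviness, center, direction)
            if np.any(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) > clearance):
                continue
            ok, mask_coords = _stamp(
                img, occupancy, _trim_for_caps(pts, width_px), width_px, spec, record_mask=True
            )
            if ok:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a {length_um:.1f}-um fiber inside the "
                f"{spec.field_diameter_um:.0f}-um field within the retry budget"
            )
        arc_um = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) * spec.scale_um_per_px
        fibers.append(
            GroundTruthFiber(
                centerline=pts,
                true_length_um=arc_um,
                true_width_um=width_um,
                is_countable=meets_criteria(arc_um, width_um, criteria=criteria),
                pixels=mask_coords,
            )
        )

    for _ in range(n_particles):
        diam_px = max(_sample_dist(rng, spec.particle_size_dist) / spec.scale_um_per_px, 1.0)
        clearance = R - (diam_px / 2.0 + 2.0)
        for _ in range(80):
            rad = clearance * math.sqrt(rng.uniform(0.0, 1.0))
            ang = rng.uniform(0.0, 2.0 * math.pi)
            pt = np.array([[cx + rad * math.cos(ang), cy + rad * math.sin(ang)]])
            ok, _ = _stamp(img, occupancy, pt, diam_px, spec, record_mask=False)
            if ok:
                break
        # particles that fail placement are silently dropped (clutter only)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    # constant grey outside the field disc, matching the background level
    yy, xx = np.mgrid[0:height, 0:width]
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 > R**2
    img[outside] = spec.background

    pixels = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    image = CalibratedImage(pixels=pixels, scale_um_per_px=spec.scale_um_per_px, field_id=field_id)

    shapes = [
        Shape(
            points=_mask_polygon(f.pixels, (width, height)),
            label=COUNTABLE if f.is_countable else SUBCRITERIA,
        )
        for f in fibers
    ]
    annotations = AnnotationSet(
        image_ref=f"{field_id}.png", image_size=(width, height), shapes=shapes
    )
    return image, fibers, annotations


def scene_to_density(spec: SceneSpec, n_scenes: int, criteria: CountingCriteria = CountingCriteria()) -> float:
    """Empirical mean countable-fiber count per field over generated scenes.

    Scene *i* uses seed ``spec.seed + i`` so the estimate is reproducible.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    total = 0
    for i in range(n_scenes):
        _, fibers, _ = generate_scene(replace(spec, noise_sd=0.0, n_particles=0), seed=spec.seed + i, criteria=criteria)
        total += sum(f.is_countable for f in fibers)
    return total / n_scenes
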