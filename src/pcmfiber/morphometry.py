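"""Fiber morphometry: rotated minimum-area rectangles, length/width under the
two measurement conventions, and pixel/micron calibration.

A fiber arrives as an explicit pixel group — an ``(n, 2)`` integer array of
``(row, col)`` indices.  Both measurement conventions start from the rotated
minimum-area rectangle enclosing the pixel centers:

* **instance style** (as produced from per-object soft masks): the width is
  the number of group pixels cut by the line through the rectangle center
  orthogonal to the long axis;
* **semantic style** (as produced from a per-pixel probability map): the
  width is the mean, along the long axis, of the per-section pixel counts in
  the short-axis direction.

Side lengths are reported in pixel-count units: the rectangle side equals the
span of pixel centers plus one (a half-pixel margin at each end), so a solid
bar 16 pixels long measures 16 px = 5.0 um at 0.3125 um/px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely import MultiPoint


@dataclass(frozen=True)
class RotatedRect:
    """Rotated rectangle: center (x, y), side lengths in pixel-count units,
    and the long-axis orientation in degrees within [0, 180)."""

    center: tuple[float, float]
    long_side_px: float
    short_side_px: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not self.long_side_px >= self.short_side_px >= 0:
            raise ValueError(
                f"need long >= short >= 0, got {self.long_side_px}, {self.short_side_px}"
            )


@dataclass
class FiberCandidate:
    """One measured fiber candidate.

    ``length_um = length_px * scale`` exactly and
    ``aspect_ratio = length_um / width_um`` arithmetically; no ordering
    between measured length and width is enforced (strongly curved fibers can
    measure wider than long).
    """

    pixels: np.ndarray
    rect: RotatedRect
    length_px: float
    width_px: float
    length_um: float
    width_um: float
    aspect_ratio: float
    convention: str
    scale_um_per_px: float
    source_probability: float | None = None
    fallback: bool = False
    contour: np.ndarray | None = None
    meets_criteria: bool | None = field(default=None)


def px_to_um(n_px: float, scale_um_per_px: float) -> float:
    """Convert a pixel count to microns: ``n_px * scale``."""
    if not scale_um_per_px > 0:
        raise ValueError(f"scale must be > 0, got {scale_um_per_px}")
    if n_px < 0:
        raise ValueError(f"pixel count must be >= 0, got {n_px}")
    return float(n_px) * float(scale_um_per_px)


def scale_from_reference(length_um: float, n_px: float) -> float:
    """Calibration from a stage-micrometer reading: um spanned / pixels spanned.

    E.g. a 10 um graticule division spanning 32 pixels gives 0.3125 um/px.
    """
    if length_um <= 0 or n_px <= 0:
        raise ValueError("reference length and pixel span must be positive")
    return float(length_um) / float(n_px)


def _as_points_xy(pixels) -> np.ndarray:
    px = np.asarray(pixels)
    if px.ndim != 2 or px.shape[1] != 2 or len(px) == 0:
        raise ValueError(f"pixel set must be non-empty (n, 2) (row, col), got shape {px.shape}")
    return np.column_stack([px[:, 1], px[:, 0]]).astype(float)


def min_area_rect(pixels) -> RotatedRect:
    """Rotated minimum-area rectangle enclosing all pixel centers.

    The search runs over convex-hull edge orientations (rotating calipers)
    minimizing the pixel-count area ``(span_u + 1) * (span_v + 1)``; the
    half-pixel margin makes side lengths count pixels.  The angle is the
    orientation of the long side, normalized to [0, 180).
    """
    pts = _as_points_xy(pixels)
    hull = MultiPoint(pts).convex_hull

    if hull.geom_type == "Point":
        x, y = pts[0]
        return RotatedRect(center=(float(x), float(y)), long_side_px=1.0, short_side_px=1.0, angle_deg=0.0)

    if hull.geom_type == "LineString":
        (x0, y0), (x1, y1) = hull.coords[0], hull.coords[-1]
        length = math.hypot(x1 - x0, y1 - y0)
        ang = math.degrees(math.atan2(y1 - y0, x1 - x0)) % 180.0
        return RotatedRect(
            center=((x0 + x1) / 2.0, (y0 + y1) / 2.0),
            long_side_px=length + 1.0,
            short_side_px=1.0,
            angle_deg=ang,
        )

    verts = np.asarray(hull.exterior.coords)[:-1]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi))

    best = None
    for theta in angles:
        c, s = math.cos(theta), math.sin(theta)
        u = verts[:, 0] * c + verts[:, 1] * s
        v = -verts[:, 0] * s + verts[:, 1] * c
        su, sv = u.max() - u.min(), v.max() - v.min()
        area = (su + 1.0) * (sv + 1.0)
        if best is None or area < best[0]:
            best = (area, theta, u.min(), u.max(), v.min(), v.max())

    _, theta, umin, umax, vmin, vmax = best
    cu, cv = (umin + umax) / 2.0, (vmin + vmax) / 2.0
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = cu * c - cv * s, cu * s + cv * c
    su, sv = umax - umin, vmax - vmin
    if su >= sv:
        long_side, short_side = su + 1.0, sv + 1.0
        ang = math.degrees(theta) % 180.0
    else:
        long_side, short_side = sv + 1.0, su + 1.0
        ang = math.degrees(theta + math.pi / 2.0) % 180.0
    return RotatedRect(center=(cx, cy), long_side_px=long_side, short_side_px=short_side, angle_deg=ang)


def _long_axis_sections(pixels, rect: RotatedRect):
    """Bin pixel centers into unit-width sections along the rectangle's long
    axis.  Returns (section index per pixel, per-section counts, index of the
    section containing the rectangle center)."""
    pts = _as_points_xy(pixels)
    theta = math.radians(rect.angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = rect.center
    u = (pts[:, 0] - cx) * c + (pts[:, 1] - cy) * s
    umin = u.min()
    sections = np.floor(u - umin + 0.5).astype(int)
    counts = np.bincount(sections)
    center_section = int(np.floor(0.0 - umin + 0.5))
    return sections, counts, center_section


def measure_instance_style(
    pixels, scale_um_per_px: float, *, source_probability: float | None = None
) -> FiberCandidate:
    """Measure a pixel group the instance-segmentation way.

    length = rectangle long side; width = the orthogonal (short-axis) pixel
    count at the rectangle center.  The count is taken as the mean of the
    populated unit-width sections in a 3-section neighborhood of the center:
    on diagonal orientations a single lattice section aliases (alternating
    sparse/dense cross-sections), and the short neighborhood suppresses that
    while remaining exact for constant-width bars.  If the whole neighborhood
    is empty (strongly curved fibers), the nearest populated section is used
    and the fallback is flagged.
    """
    rect = min_area_rect(pixels)
    _, counts, center_section = _long_axis_sections(pixels, rect)

    lo = max(center_section - 1, 0)
    window = counts[lo : center_section + 2]
    window = window[window > 0] if window.size else window

    fallback = window.size == 0
    if fallback:
        populated = np.flatnonzero(counts)
        # nearest populated section; ties toward the lower index
        idx = int(populated[np.argmin(np.abs(populated - center_section))])
        width_px = float(counts[idx])
    else:
        width_px = float(window.mean())

    return _candidate(pixels, rect, width_px, scale_um_per_px, "instance_style",
                      source_probability, fallback)


def measure_semantic_style(
    pixels, scale_um_per_px: float, *, source_probability: float | None = None
) -> FiberCandidate:
    """Measure a pixel group the semantic-segmentation way.

    length = rectangle long side; width = mean over long-axis sections of the
    short-axis pixel count in that section.  Sections containing no group
    pixels are excluded from the mean (including them would underestimate the
    width of C-shaped fibers).
    """
    rect = min_area_rect(pixels)
    _, counts, _ = _long_axis_sections(pixels, rect)
    populated = counts[counts > 0]
    width_px = float(populated.mean())
    return _candidate(pixels, rect, width_px, scale_um_per_px, "semantic_style",
                      source_probability, False)


def _candidate(pixels, rect, width_px, scale, convention, source_probability, fallback):
    length_px = float(rect.long_side_px)
    length_um = px_to_um(length_px, scale)
    width_um = px_to_um(width_px, scale)
    return FiberCandidate(
        pixels=np.asarray(pixels),
        rect=rect,
        length_px=length_px,
        width_px=width_px,
        length_um=length_um,
        width_um=width_um,
        aspect_ratio=length_um / width_um,
        convention=convention,
        scale_um_per_px=scale,
        source_probability=source_probability,
        fallback=fallback,
    )


def measure(pixels, scale_um_per_px: float, convention: str = "semantic_style", **kw) -> FiberCandidate:
    """Dispatch to the requested measurement convention."""
    if convention == "instance_style":
        return measure_instance_style(pixels, scale_um_per_px, **kw)
    if convention == "semantic_style":
        return measure_semantic_style(pixels, scale_um_per_px, **kw)
    raise ValueError(f"unknown convention {convention!r}")
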