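"""Raster, annotation, and report I/O for PCM fiber-counting workflows.

Coordinate convention (used throughout the package): pixel coordinates are
0-based with ``x`` = column and ``y`` = row; the center of pixel ``(row, col)``
sits at continuous coordinates ``(x=col, y=row)``, so the raster of a
``W x H`` image spans ``[-0.5, W-0.5] x [-0.5, H-0.5]``.  Polygon vertices live
in this continuous space.  Rasterization includes every pixel whose center lies
inside or on the boundary of the polygon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon

COUNTABLE = "countable_fiber"
SUBCRITERIA = "subcriteria_fiber"
LABEL_VOCABULARY = (COUNTABLE, SUBCRITERIA)

#: Default mapping from free-text annotation labels onto the two-value
#: vocabulary.  Unknown labels map to ``countable_fiber`` with the original
#: label preserved in the shape's notes.
DEFAULT_LABEL_MAP = {
    COUNTABLE: COUNTABLE,
    SUBCRITERIA: SUBCRITERIA,
    "fiber": COUNTABLE,
    "countable": COUNTABLE,
    "sub_criteria_fiber": SUBCRITERIA,
    "subcriteria": SUBCRITERIA,
    "short_fiber": SUBCRITERIA,
}

# ITU-R BT.601 luma weights, the fixed documented RGB->grayscale rule.
_LUMA = np.array([0.299, 0.587, 0.114])


class LabelMeParseError(ValueError):
    """Raised when a LabelMe JSON file is malformed."""


class AnnotationError(ValueError):
    """Raised when an annotation shape violates the type invariants."""


@dataclass
class CalibratedImage:
    """A grayscale field-of-view raster with its physical calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D uint8 (or float) intensity raster, indexed ``[row, col]``.
    scale_um_per_px : float
        Microns per pixel; 0.3125 corresponds to 10 um spanning 32 pixels
        at 400x magnification.
    field_id : str
        Identifier of the observed field, e.g. ``"Amo-1-B1"`` in the
        row-column naming of a 50-field counting coverslip.
    """

    pixels: np.ndarray
    scale_um_per_px: float = 0.3125
    field_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not self.scale_um_per_px > 0:
            raise ValueError(f"scale_um_per_px must be > 0, got {self.scale_um_per_px}")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class Shape:
    """One annotated polygon: vertices in (x, y) pixel coordinates."""

    points: np.ndarray
    label: str
    notes: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise AnnotationError(f"polygon points must be (n, 2), got {self.points.shape}")
        if len(self.points) < 3:
            raise AnnotationError(f"polygon needs >=3 vertices, got {len(self.points)}")
        if self.label not in LABEL_VOCABULARY:
            raise AnnotationError(f"label {self.label!r} not in {LABEL_VOCABULARY}")


@dataclass
class AnnotationSet:
    """Expert ground truth for one image: labeled polygons.

    ``image_size`` is (width_px, height_px).  Vertices must lie within the
    continuous raster extent ``[-0.5, W-0.5] x [-0.5, H-0.5]``.
    """

    image_ref: str
    image_size: tuple[int, int]
    shapes: list[Shape] = field(default_factory=list)

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise AnnotationError(f"image_size must be positive, got {self.image_size}")
        for i, shp in enumerate(self.shapes):
            x, y = shp.points[:, 0], shp.points[:, 1]
            if (x < -0.5).any() or (x > w - 0.5).any() or (y < -0.5).any() or (y > h - 0.5).any():
                raise AnnotationError(
                    f"shape {i}: vertices outside image bounds {w}x{h}"
                )

    def countable(self) -> list[Shape]:
        return [s for s in self.shapes if s.label == COUNTABLE]

    def subcriteria(self) -> list[Shape]:
        return [s for s in self.shapes if s.label == SUBCRITERIA]


def read_labelme(path, label_map: dict[str, str] | None = None) -> AnnotationSet:
    """Read a LabelMe polygon-JSON annotation file.

    Labels are mapped onto the two-value vocabulary through ``label_map``
    (default :data:`DEFAULT_LABEL_MAP`); labels absent from the map become
    ``countable_fiber`` with the original label recorded in the shape notes.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LabelMeParseError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("imagePath", "imageHeight", "imageWidth", "shapes"):
        if key not in data:
            raise LabelMeParseError(f"{path}: missing required key {key!r}")
    lmap = DEFAULT_LABEL_MAP if label_map is None else label_map

    shapes: list[Shape] = []
    for i, raw in enumerate(data["shapes"]):
        if "points" not in raw or "label" not in raw:
            raise LabelMeParseError(f"{path}: shape {i} missing 'points' or 'label'")
        pts = raw["points"]
        if len(pts) < 3:
            raise AnnotationError(f"{path}: shape {i} has {len(pts)} < 3 points")
        raw_label = raw["label"]
        notes = raw.get("description") or None
        label = lmap.get(raw_label)
        if label is None:
            label = COUNTABLE
            extra = f"original label: {raw_label}"
            notes = f"{notes}; {extra}" if notes else extra
        shapes.append(Shape(points=np.asarray(pts, dtype=float), label=label, notes=notes))

    return AnnotationSet(
        image_ref=data["imagePath"],
        image_size=(int(data["imageWidth"]), int(data["imageHeight"])),
        shapes=shapes,
    )


def write_labelme(annotations: AnnotationSet, path) -> Path:
    """Write an AnnotationSet as LabelMe-schema JSON (lossless round-trip)."""
    path = Path(path)
    w, h = annotations.image_size
    shapes = []
    for shp in annotations.shapes:
        entry = {
            "label": shp.label,
            "points": [[float(x), float(y)] for x, y in shp.points],
            "group_id": None,
            "shape_type": "polygon",
            "flags": {},
        }
        if shp.notes:
            entry["description"] = shp.notes
        shapes.append(entry)
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": shapes,
        "imagePath": annotations.image_ref,
        "imageData": None,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def polygons_to_mask(
    annotations: AnnotationSet, image_size: tuple[int, int] | None = None
) -> np.ndarray:
    """Rasterize polygons to a labeled mask (0 = background, k = shape k).

    Fill rule: a pixel belongs to shape *k* if its center lies inside or on
    the boundary of polygon *k*.  Overlapping shapes are resolved by drawing
    in order, so the later shape wins.  Zero-area polygons are skipped with a
    warning.
    """
    w, h = image_size if image_size is not None else annotations.image_size
    mask = np.zeros((h, w), dtype=np.int32)
    for k, shp in enumerate(annotations.shapes, start=1):
        poly = Polygon(shp.points)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area == 0:
            warnings.warn(f"shape {k - 1} has zero area; skipped", stacklevel=2)
            continue
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.ceil(minx - 0.5)), 0)
        c1 = min(int(np.floor(maxx + 0.5)), w - 1)
        r0 = max(int(np.ceil(miny - 0.5)), 0)
        r1 = min(int(np.floor(maxy + 0.5)), h - 1)
        if c1 < c0 or r1 < r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        # intersects == covers for points: boundary-inclusive test of centers
        inside = shapely.intersects_xy(poly, cols.ravel(), rows.ravel())
        sub = mask[r0 : r1 + 1, c0 : c1 + 1].ravel()
        sub[inside] = k
        mask[r0 : r1 + 1, c0 : c1 + 1] = sub.reshape(rows.shape)
    return mask


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Fixed luma rule (ITU-R BT.601): 0.299 R + 0.587 G + 0.114 B, rounded."""
    return np.round(rgb[..., :3].astype(float) @ _LUMA).astype(np.uint8)


def read_image(path, scale_um_per_px: float = 0.3125, field_id: str | None = None) -> CalibratedImage:
    """Load a JPEG/PNG micrograph as a grayscale CalibratedImage."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "L":
                pixels = np.asarray(im)
            elif im.mode in ("RGB", "RGBA"):
                pixels = rgb_to_gray(np.asarray(im))
            else:
                pixels = np.asarray(im.convert("L"))
    except UnidentifiedImageError as exc:
        raise ValueError(f"unsupported raster format: {path.suffix!r} ({path})") from exc
    return CalibratedImage(
        pixels=pixels,
        scale_um_per_px=scale_um_per_px,
        field_id=field_id if field_id is not None else path.stem,
    )


def write_image(image: CalibratedImage, path) -> Path:
    """Write a CalibratedImage raster as PNG/JPEG."""
    path = Path(path)
    Image.fromarray(np.asarray(image.pixels, dtype=np.uint8), mode="L").save(path)
    return path


def write_report(report, csv_path, json_path=None) -> Path:
    """Write a MatchReport as CSV (per-image rows + Total row), optional JSON.

    Column order follows the standard bookkeeping layout:
    image, expert_count, counted, overlooked, overcounted.
    """
    csv_path = Path(csv_path)
    frame = report.to_frame()
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_dict(), indent=2))
    return csv_path
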