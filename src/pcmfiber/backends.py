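"""Segmentation backends: post-processing of semantic and instance model
outputs into explicit pixel groups, plus a deterministic classical detector.

Two output contracts are supported:

* semantic: one per-pixel fiber-probability map for the whole image; pixels
  with probability strictly greater than the threshold (default 0.5) form
  fibers as connected components;
* instance: a list of per-object detections, each with a class probability
  and a soft mask; detections with class probability strictly greater than
  0.5 are kept, and within each the pixels with mask value >= 0.8 form the
  fiber.  (Note the deliberate asymmetry: the class cut is strict, the mask
  cut inclusive.)

The classical detector is a training-free stand-in so the pipeline runs end
to end without a neural model: it is a documented chain of background
flattening, smoothing and soft thresholding, deterministic for fixed
parameters, producing a semantic-style pseudo-probability map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit
from skimage import measure as skmeasure

from .io import CalibratedImage

logger = logging.getLogger(__name__)


@dataclass
class SemanticOutput:
    """Per-pixel fiber probability map in [0, 1]."""

    prob_map: np.ndarray

    def __post_init__(self) -> None:
        self.prob_map = np.asarray(self.prob_map, dtype=float)
        if self.prob_map.ndim != 2:
            raise ValueError(f"prob_map must be 2-D, got shape {self.prob_map.shape}")
        if self.prob_map.min() < 0 or self.prob_map.max() > 1:
            raise ValueError("prob_map values must lie in [0, 1]")


@dataclass
class Instance:
    """One detected object: class probability plus a soft mask.

    The mask may cover the full image (``origin=(0, 0)``) or a sub-raster
    whose top-left pixel sits at ``origin=(row, col)``.
    """

    class_probability: float
    mask: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=float)
        if not 0 <= self.class_probability <= 1:
            raise ValueError(f"class_probability must be in [0, 1], got {self.class_probability}")
        if self.mask.ndim != 2 or self.mask.min() < 0 or self.mask.max() > 1:
            raise ValueError("soft mask must be 2-D with values in [0, 1]")


@dataclass
class InstanceOutput:
    """Instance-segmentation output: a list of detections."""

    instances: list[Instance] = field(default_factory=list)


def semantic_postprocess(
    out: SemanticOutput,
    p_threshold: float = 0.5,
    connectivity: int = 8,
    min_pixels: int = 1,
) -> list[np.ndarray]:
    """Extract fiber pixel groups from a probability map.

    Pixels with probability strictly greater than ``p_threshold`` are kept
    and grouped into connected components (8-connectivity by default, so
    diagonal fiber runs stay connected).  Components smaller than
    ``min_pixels`` are dropped and logged.  Each group is an ``(n, 2)``
    integer array of (row, col), in lexicographic order.
    """
    if not 0 <= p_threshold <= 1:
        raise ValueError(f"p_threshold must be in [0, 1], got {p_threshold}")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    binary = out.prob_map > p_threshold
    labels = skmeasure.label(binary, connectivity=1 if connectivity == 4 else 2)
    groups = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_pixels:
            logger.info("dropping component of %d px (< %d)", len(coords), min_pixels)
            continue
        groups.append(coords)
    return groups


def instance_postprocess(
    out: InstanceOutput,
    class_threshold: float = 0.5,
    mask_threshold: float = 0.8,
) -> list[np.ndarray]:
    """Extract fiber pixel groups from instance detections.

    Keeps instances with class probability strictly greater than
    ``class_threshold``; within each, the group is the set of pixels whose
    soft-mask value is greater than or equal to ``mask_threshold``.  Empty
    groups are dropped and logged.
    """
    for name, value in (("class_threshold", class_threshold), ("mask_threshold", mask_threshold)):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    groups = []
    for k, inst in enumerate(out.instances):
        if not inst.class_probability > class_threshold:
            continue
        coords = np.argwhere(inst.mask >= mask_threshold)
        if len(coords) == 0:
            logger.info("instance %d passed class cut but has empty mask; dropped", k)
            continue
        coords = coords + np.asarray(inst.origin, dtype=int)
        groups.append(coords)
    return groups


@dataclass(frozen=True)
class ClassicalParams:
    """Parameters of the classical ridge/contrast detector.

    smooth_sigma : Gaussian presmoothing of the darkness map, px.
    rel_level : detection level as a fraction of the robust peak darkness;
        0.4 places the soft threshold slightly outside the half-depth
        contour of a fiber's intensity dip.
    softness : logistic softness as a fraction of the detection level.
    min_contrast : minimum robust peak darkness (intensity units in [0, 1])
        below which the field is declared empty — guards against pure noise.
    """

    smooth_sigma: float = 0.7
    rel_level: float = 0.4
    softness: float = 0.125
    min_contrast: float = 0.08


def classical_detect(image: CalibratedImage, params: ClassicalParams = ClassicalParams()) -> SemanticOutput:
    """Deterministic classical fiber detector producing a pseudo-probability map.

    Chain: normalize to [0, 1]; estimate the background as the median grey
    level; form the darkness map (background minus image, clipped at 0);
    Gaussian-smooth it; set the operating level at ``rel_level`` times the
    99.9th-percentile darkness and map through a logistic.  Fields whose
    robust peak darkness falls below ``min_contrast`` return an all-zero map.
    """
    img = np.asarray(image.pixels, dtype=float)
    if img.ndim != 2:
        raise ValueError("classical_detect requires a grayscale image")
    if img.max() > 1.0:
        img = img / 255.0
    background = float(np.median(img))
    darkness = np.clip(background - img, 0.0, None)
    darkness = ndimage.gaussian_filter(darkness, sigma=params.smooth_sigma)
    peak = float(np.percentile(darkness, 99.9))
    if peak < params.min_contrast:
        return SemanticOutput(prob_map=np.zeros_like(img))
    level = params.rel_level * peak
    softness = max(params.softness * level, 1e-9)
    prob = expit((darkness - level) / softness)
    return SemanticOutput(prob_map=np.clip(prob, 0.0, 1.0))
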