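"""End-to-end orchestration: detect -> measure -> count -> evaluate.

`run_pipeline` is a pure library function (the CLI wraps it): given a
directory of field-of-view images (plus optional LabelMe annotations) it
runs the classical detection backend, measures every pixel group under the
configured convention, applies the counting criteria, and — when annotations
are present — produces the counted/overlooked/overcounted report with pooled
recall and precision.  All outputs are deterministic functions of the
configuration and the inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backends import ClassicalParams, classical_detect, semantic_postprocess
from .counting import (
    CountingCriteria,
    SamplingConfig,
    apply_criteria,
    concentration_fibers_per_L,
    round_half_up,
)
from .evaluation import match_detections, tabulate
from .io import AnnotationSet, polygons_to_mask, read_image, read_labelme, write_report
from .morphometry import measure

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class PipelineConfig:
    """Everything that determines the numeric output of a pipeline run."""

    scale_um_per_px: float = 0.3125
    convention: str = "semantic_style"
    criteria: CountingCriteria = field(default_factory=CountingCriteria)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    detector: ClassicalParams = field(default_factory=ClassicalParams)
    p_threshold: float = 0.5
    connectivity: int = 8
    iou_threshold: float = 0.5
    iou_mode: str = "union"
    match_strategy: str = "greedy"
    include_subcriteria: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, typ in (("criteria", CountingCriteria), ("sampling", SamplingConfig),
                         ("detector", ClassicalParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def truth_pixel_groups(annotations: AnnotationSet, include_subcriteria: bool = False):
    """Rasterize annotation polygons into per-fiber pixel groups."""
    shapes = annotations.shapes if include_subcriteria else annotations.countable()
    subset = AnnotationSet(
        image_ref=annotations.image_ref, image_size=annotations.image_size, shapes=shapes
    )
    mask = polygons_to_mask(subset)
    groups = []
    for k in range(1, len(shapes) + 1):
        coords = np.argwhere(mask == k)
        if len(coords):
            groups.append(coords)
        else:
            warnings.warn(f"truth shape {k - 1} rasterized to zero pixels; dropped", stacklevel=2)
    return groups


def process_image(image, config: PipelineConfig):
    """Detect and measure one CalibratedImage; returns FiberCandidate list
    with ``meets_criteria`` populated."""
    semantic = classical_detect(image, config.detector)
    groups = semantic_postprocess(
        semantic, p_threshold=config.p_threshold, connectivity=config.connectivity
    )
    candidates = []
    for g in groups:
        cand = measure(g, config.scale_um_per_px, convention=config.convention)
        cand.meets_criteria = apply_criteria(cand, config.criteria)
        candidates.append(cand)
    return candidates


def run_pipeline(
    config: PipelineConfig,
    input_dir,
    out_dir=None,
    evaluate: bool = False,
) -> dict:
    """Run the full pipeline over a directory of field images.

    When ``evaluate`` is set, every image must have a LabelMe JSON sidecar
    with the same stem; missing sidecars raise a FileNotFoundError listing
    them all.  Returns a bundle dict with the measurement table, per-field
    counts, the concentration estimate, and (when evaluating) the
    MatchReport; files are written under ``out_dir`` when given.
    """
    input_dir = Path(input_dir)
    images = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not images:
        raise FileNotFoundError(f"no images ({'/'.join(IMAGE_SUFFIXES)}) in {input_dir}")

    if evaluate:
        missing = [str(p.with_suffix(".json")) for p in images if not p.with_suffix(".json").exists()]
        if missing:
            raise FileNotFoundError(
                "evaluation requested but annotation files are missing: " + ", ".join(missing)
            )

    rows = []
    per_field_counts = []
    image_matches = []
    for path in images:
        image = read_image(path, scale_um_per_px=config.scale_um_per_px)
        candidates = process_image(image, config)
        countable = [c for c in candidates if c.meets_criteria]
        per_field_counts.append(len(countable))
        for i, c in enumerate(candidates):
            rows.append(
                {
                    "image": image.field_id,
                    "id": i,
                    "convention": c.convention,
                    "length_um": c.length_um,
                    "width_um": c.width_um,
                    "aspect_ratio": c.aspect_ratio,
                    "meets_criteria": bool(c.meets_criteria),
                    "fallback": bool(c.fallback),
                }
            )
        if evaluate:
            annotations = read_labelme(path.with_suffix(".json"))
            truth = truth_pixel_groups(annotations, config.include_subcriteria)
            preds = [c.pixels for c in (candidates if config.include_subcriteria else countable)]
            image_matches.append(
                match_detections(
                    preds,
                    truth,
                    iou_threshold=config.iou_threshold,
                    mode=config.iou_mode,
                    strategy=config.match_strategy,
                    image_id=image.field_id,
                )
            )

    measurements = pd.DataFrame(
        rows,
        columns=["image", "id", "convention", "length_um", "width_um",
                 "aspect_ratio", "meets_criteria", "fallback"],
    )
    mean_per_field = float(np.mean(per_field_counts))
    concentration = concentration_fibers_per_L(mean_per_field, config.sampling)

    bundle = {
        "measurements": measurements,
        "per_field_counts": per_field_counts,
        "mean_fibers_per_field": mean_per_field,
        "concentration_fibers_per_L": concentration,
        "concentration_rounded": round_half_up(concentration, 1),
        "report": tabulate(image_matches) if evaluate else None,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        measurements.to_csv(out_dir / "measurements.csv", index=False)
        (out_dir / "concentration.json").write_text(
            json.dumps(
                {
                    "mean_fibers_per_field": mean_per_field,
                    "fibers_per_L": concentration,
                    "fibers_per_L_rounded": bundle["concentration_rounded"],
                    "sampling": asdict(config.sampling),
                },
                indent=2,
            )
        )
        if evaluate:
            write_report(bundle["report"], out_dir / "report.csv", out_dir / "report.json")
        (out_dir / "runlog.json").write_text(
            json.dumps(
                {
                    "config": config.to_dict(),
                    "config_digest": config.digest(),
                    "pcmfiber_version": __version__,
                    "numpy_version": np.__version__,
                    "n_images": len(images),
                },
                indent=2,
            )
        )
    return bundle
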