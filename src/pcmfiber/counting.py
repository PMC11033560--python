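"""Regulatory fiber-counting criteria and airborne-concentration conversion.

A countable fiber under the Japanese asbestos-monitoring convention has
length >= 5 um (inclusive), width < 3 um (strict), and aspect ratio >= 3
(inclusive).  Counts per 300-um field of view convert to an airborne
concentration in fibers/L through the ratio of the filter's effective
collection area to the field area and the sampled air volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass(frozen=True)
class CountingCriteria:
    """Countable-fiber definition.  Inclusivities: length >= min_length_um,
    width < max_width_um (strict), aspect >= min_aspect_ratio."""

    min_length_um: float = 5.0
    max_width_um: float = 3.0
    min_aspect_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not (self.min_length_um > 0 and self.max_width_um > 0 and self.min_aspect_ratio > 0):
            raise ValueError("criteria thresholds must be positive")


@dataclass(frozen=True)
class SamplingConfig:
    """Air-sampling geometry for the fibers/L conversion.

    ``effective_diameter_mm`` is the diameter of the filter area actually
    exposed to airflow; 35 mm is the standard effective diameter of a 47-mm
    membrane filter in its holder.
    """

    air_volume_L: float = 2400.0
    filter_diameter_mm: float = 47.0
    effective_diameter_mm: float = 35.0
    field_diameter_um: float = 300.0

    def __post_init__(self) -> None:
        if min(self.air_volume_L, self.filter_diameter_mm,
               self.effective_diameter_mm, self.field_diameter_um) <= 0:
            raise ValueError("sampling parameters must be positive")
        if self.effective_diameter_mm > self.filter_diameter_mm:
            raise ValueError("effective diameter cannot exceed filter diameter")

    @property
    def fields_per_filter(self) -> float:
        """Ratio of effective filter area to one field-of-view area."""
        eff_um = self.effective_diameter_mm * 1000.0
        return (eff_um / self.field_diameter_um) ** 2


def meets_criteria(
    length_um: float,
    width_um: float,
    aspect_ratio: float | None = None,
    criteria: CountingCriteria = CountingCriteria(),
) -> bool:
    """Apply the counting criteria to raw dimensions.

    ``aspect_ratio`` defaults to ``length_um / width_um``.
    """
    if length_um is None or width_um is None:
        raise ValueError("length_um and width_um are required")
    if aspect_ratio is None:
        aspect_ratio = length_um / width_um
    return (
        length_um >= criteria.min_length_um
        and width_um < criteria.max_width_um
        and aspect_ratio >= criteria.min_aspect_ratio
    )


def apply_criteria(fiber, criteria: CountingCriteria = CountingCriteria()) -> bool:
    """True iff a measured fiber candidate satisfies the counting criteria."""
    for attr in ("length_um", "width_um", "aspect_ratio"):
        if getattr(fiber, attr, None) is None:
            raise ValueError(f"fiber is missing measurement {attr!r}")
    return meets_criteria(fiber.length_um, fiber.width_um, fiber.aspect_ratio, criteria)


def count_field(fibers, criteria: CountingCriteria = CountingCriteria()) -> tuple[int, int]:
    """Partition a field's candidates into (countable, sub-criteria) counts."""
    countable = sum(apply_criteria(f, criteria) for f in fibers)
    return countable, len(fibers) - countable


def concentration_fibers_per_L(
    mean_fibers_per_field: float, sampling: SamplingConfig = SamplingConfig()
) -> float:
    """Airborne fiber concentration in fibers per liter of sampled air.

    ``mean_per_field * (effective filter area / field area) / air volume``,
    with both areas as circle areas of the configured diameters.
    """
    if mean_fibers_per_field < 0:
        raise ValueError("mean fibers per field must be >= 0")
    eff_um = sampling.effective_diameter_mm * 1000.0
    area_ratio = (math.pi * (eff_um / 2.0) ** 2) / (
        math.pi * (sampling.field_diameter_um / 2.0) ** 2
    )
    return mean_fibers_per_field * area_ratio / sampling.air_volume_L


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention used for reported concentrations."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
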