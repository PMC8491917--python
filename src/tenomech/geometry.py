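"""Cross-sectional areas and the bulk ratio of a tenorrhaphy.

The bulk ratio compares the repaired segment's cross-section with the native
tendons' — a proxy for gliding resistance and adhesion risk. Areas come from
an elliptical model on the two orthogonal caliper diameters; a circular
fallback handles specimens with a single recorded diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from tenomech.io import SpecimenGeometry, ValidationError

__all__ = ["BulkResult", "bulk_ratio", "bulk_result", "cross_sectional_area"]


@dataclass(frozen=True)
class BulkResult:
    """Areas (mm^2) and bulk ratio (%) of one specimen."""

    specimen_id: str
    area_donor: float
    area_recipient: float
    area_repair: float
    bulk_ratio: float  # percent

    def __post_init__(self) -> None:
        if min(self.area_donor, self.area_recipient, self.area_repair) <= 0:
            raise ValidationError(f"{self.specimen_id}: areas must be > 0")
        if self.bulk_ratio <= 0:
            raise ValidationError(f"{self.specimen_id}: bulk ratio must be > 0")


def cross_sectional_area(d1: float, d2: float | None = None) -> float:
    """Elliptical cross-section from two orthogonal diameters, mm^2.

    ``area = pi * d1 * d2 / 4``; with a single diameter the section is taken
    as circular (d2 = d1).
    """
    if d2 is None:
        d2 = d1
    if d1 <= 0 or d2 <= 0:
        raise ValidationError("diameters must be > 0")
    return math.pi * d1 * d2 / 4.0


def bulk_ratio(area_repair: float, area_donor: float, area_recipient: float,
               denominator: str = "sum") -> float:
    """Bulk ratio in percent: repair area over the native tendons' area.

    ``denominator="sum"`` (default) divides by the summed donor and
    recipient areas; ``"mean"`` divides by their mean. The ratio is not
    clamped: repairs slimmer than the combined natives give values below
    100%.
    """
    if min(area_repair, area_donor, area_recipient) <= 0:
        raise ValidationError("areas must be > 0")
    if denominator == "sum":
        denom = area_donor + area_recipient
    elif denominator == "mean":
        denom = (area_donor + area_recipient) / 2.0
    else:
        raise ValidationError(f"unknown denominator convention {denominator!r}")
    return 100.0 * area_repair / denom


def bulk_result(geometry: SpecimenGeometry, denominator: str = "sum") -> BulkResult:
    """Areas and bulk ratio from one specimen's caliper measurements."""
    a_d = cross_sectional_area(geometry.d_donor_1, geometry.d_donor_2)
    a_r = cross_sectional_area(geometry.d_recip_1, geometry.d_recip_2)
    a_s = cross_sectional_area(geometry.d_repair_1, geometry.d_repair_2)
    return BulkResult(
        specimen_id=geometry.specimen_id,
        area_donor=a_d, area_recipient=a_r, area_repair=a_s,
        bulk_ratio=bulk_ratio(a_s, a_d, a_r, denominator),
    )
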