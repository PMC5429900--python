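"""Calibrated areas and derived relative parameters per section.

Absolute compartment areas are pixel counts scaled by the square of the
spatial calibration (um/px).  Derived parameters follow the standard plaque
morphometry formulas: total vessel area = media + lumen + plaque; relative
lumen/plaque/media = compartment / total vessel area x 100%; relative
collagen/lipid = compartment / plaque area x 100%.

Ratios with a zero denominator are explicitly undefined (``None``), never
silently zero: a plaque-free section must not masquerade as a collagen-free
plaque.  Full floating precision is kept internally; two-decimal rendering is
presentation only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

logger = logging.getLogger(__name__)

COMPARTMENTS = ("media", "lumen", "plaque", "collagen", "lipid")


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of the micrograph."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0 and math.isfinite(self.microns_per_pixel)):
            raise MorphometryError("microns_per_pixel must be positive and finite")

    @property
    def area_scale(self) -> float:
        """um^2 per pixel."""
        return self.microns_per_pixel**2


@dataclass
class MorphometryRecord:
    """Calibrated absolute areas (um^2) and relative parameters (%) of one section."""

    section_id: str
    segment_label: str = "unspecified"  # proximal | distal | unspecified
    media_area: float = 0.0
    lumen_area: float = 0.0
    plaque_area: float = 0.0
    collagen_area: float | None = None
    lipid_area: float | None = None
    total_vessel_area: float = 0.0
    relative_media: float | None = None
    relative_lumen: float | None = None
    relative_plaque: float | None = None
    relative_collagen: float | None = None
    relative_lipid: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _pct(numerator: float, denominator: float) -> float | None:
    return None if denominator == 0 else numerator / denominator * 100.0


def morphometry_from_areas(
    media_area: float,
    lumen_area: float,
    plaque_area: float,
    collagen_area: float | None = None,
    lipid_area: float | None = None,
    section_id: str = "",
    segment_label: str = "unspecified",
) -> MorphometryRecord:
    """Build a record from absolute compartment areas (um^2).

    This is the formula layer: it is also the entry point for re-deriving the
    relative parameters printed in a figure legend from its absolute areas.
    """
    for name, value in (("media", media_area), ("lumen", lumen_area), ("plaque", plaque_area)):
        if value < 0:
            raise MorphometryError(f"{name}_area must be non-negative")
    total = media_area + lumen_area + plaque_area
    if total == 0:
        raise MorphometryError("zero total vessel area")
    if plaque_area == 0 and (collagen_area or lipid_area):
        logger.warning(
            "plaque area is zero: relative collagen/lipid are undefined "
            "despite nonzero compartment areas"
        )
    return MorphometryRecord(
        section_id=section_id,
        segment_label=segment_label,
        media_area=media_area,
        lumen_area=lumen_area,
        plaque_area=plaque_area,
        collagen_area=collagen_area,
        lipid_area=lipid_area,
        total_vessel_area=total,
        relative_media=_pct(media_area, total),
        relative_lumen=_pct(lumen_area, total),
        relative_plaque=_pct(plaque_area, total),
        relative_collagen=None if collagen_area is None else _pct(collagen_area, plaque_area),
        relative_lipid=None if lipid_area is None else _pct(lipid_area, plaque_area),
    )


def compute_morphometry(
    seg,
    cal: Calibration,
    section_id: str = "",
    segment_label: str = "unspecified",
) -> MorphometryRecord:
    """Convert a :class:`~omsbseg.segmentation.SegmentationResult` into calibrated areas."""
    s = cal.area_scale
    return morphometry_from_areas(
        media_area=float(seg.media.sum()) * s,
        lumen_area=float(seg.lumen.sum()) * s,
        plaque_area=float(seg.plaque_area_px) * s,
        collagen_area=float(seg.collagen_in_plaque.sum()) * s,
        lipid_area=float(seg.lipid.sum()) * s,
        section_id=section_id,
        segment_label=segment_label,
    )


def auto_manual_agreement(
    auto: MorphometryRecord, manual: MorphometryRecord
) -> dict[str, float | None]:
    """Relative percent difference |auto - manual| / manual x 100 per compartment.

    Compartments absent from either record, or with a zero manual reference,
    are undefined (``None``).
    """
    out: dict[str, float | None] = {}
    for name in COMPARTMENTS:
        a = getattr(auto, f"{name}_area")
        m = getattr(manual, f"{name}_area")
        if a is None or m is None or m == 0:
            out[name] = None
        else:
            out[name] = abs(a - m) / m * 100.0
    return out


def format_record(record: MorphometryRecord) -> str:
    """Two-decimal display rendering (round-half-even), one line per parameter."""
    lines = [f"section {record.section_id or '<unnamed>'} ({record.segment_label})"]
    for name in ("media", "lumen", "plaque", "collagen", "lipid"):
        area = getattr(record, f"{name}_area")
        rel_name = f"relative_{name}"
        rel = getattr(record, rel_name, None)
        if area is None:
            continue
        rel_txt = "undefined" if rel is None else f"{rel:.2f}%"
        lines.append(f"  {name:<8s} {area:>12.1f} um^2   {rel_txt}")
    lines.append(f"  {'total':<8s} {record.total_vessel_area:>12.1f} um^2")
    return "\n".join(lines)
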