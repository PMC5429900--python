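"""Lamina detection and mask construction for artery cross-sections.

The segmentation follows the stain semantics of the OMSB method.  Elastic
laminae are thin purple closed rings; the vessel media is the area between the
innermost and outermost lamina; the internal vessel area (everything strictly
inside the inner lamina) splits into lumen (white areas containing
yellow-stained erythrocytes) and plaque; plaque area is obtained by
subtraction, lipid vacuoles are the erythrocyte-free white areas inside the
plaque, and intraplaque collagen is the blue-thresholded area inside the
plaque.

Conventions: row-major arrays, origin top-left, 0-based indices; areas are
pixel counts.  Foreground components use 8-connectivity, interior filling uses
4-connectivity (the standard complementary pair that avoids topological
paradoxes when filling rings).  The inner lamina's own pixels are assigned to
the media: the lamina outlines the internal area but does not belong to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import perimeter as sk_perimeter
from skimage.morphology import closing as morphological_closing
from skimage.morphology import disk

from .color import ClassMap, ColorConfig, StainClass, class_mask, classify_pixels

logger = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when the mask algebra cannot be established."""


class NoVesselError(SegmentationError):
    """No closed elastic lamina found.

    Carries diagnostics: number of candidate components and the largest
    enclosed area observed, to help tune thresholds.
    """

    def __init__(self, n_components: int, largest_enclosed_area: int):
        self.n_components = n_components
        self.largest_enclosed_area = largest_enclosed_area
        super().__init__(
            "no vessel detected: no closed elastic lamina passed the geometric "
            f"criteria ({n_components} candidate components, largest enclosed "
            f"area {largest_enclosed_area} px)"
        )


@dataclass
class Lamina:
    """One elastic lamina: a thin closed-ring connected component."""

    component: np.ndarray  # bool, the ring pixels (after closing)
    filled: np.ndarray  # bool, component plus its 4-connected interior
    interior: np.ndarray  # bool, strict interior = filled & ~component
    enclosed_area: int  # pixels of the strict interior
    mean_thickness: float  # px, estimated from the distance transform
    elongation: float  # perimeter^2 / area shape descriptor
    centroid: tuple[float, float]  # (row, col)

    @property
    def is_closed_ring(self) -> bool:
        return self.enclosed_area > 0


@dataclass
class LaminaSet:
    """Laminae ordered by enclosed area (ascending); ends delimit the media."""

    laminae: list[Lamina]

    def __post_init__(self) -> None:
        if not self.laminae:
            raise SegmentationError("LaminaSet must contain at least one lamina")

    @property
    def innermost(self) -> Lamina:
        return self.laminae[0]

    @property
    def outermost(self) -> Lamina:
        return self.laminae[-1]

    def __len__(self) -> int:
        return len(self.laminae)


@dataclass
class SegmentationParams:
    """Geometric parameters of the segmentation.

    ``min_rbc_pixels`` defaults to 10 px at 0.5 um/px; use
    :meth:`for_calibration` to rescale it for other resolutions (the pixel
    footprint of one erythrocyte scales with the inverse square of the
    calibration).
    """

    min_enclosed_area: int = 500
    closing_radius: int = 3
    max_thickness: float = 25.0
    min_rbc_pixels: int = 10
    allow_single_lamina: bool = False

    @classmethod
    def for_calibration(cls, microns_per_pixel: float, **overrides) -> "SegmentationParams":
        if microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        scale = (0.5 / microns_per_pixel) ** 2
        params = cls(**overrides)
        params.min_rbc_pixels = max(1, round(10 * scale))
        return params


@dataclass
class SegmentationResult:
    """Named binary masks of one segmented section.

    Invariants (checked by :meth:`validate`): media and internal are disjoint;
    lumen, lipid and collagen_in_plaque are subsets of internal; lumen and
    lipid are disjoint; collagen_in_plaque avoids the lumen; plaque pixels are
    the internal pixels not in the lumen.
    """

    media: np.ndarray
    internal: np.ndarray
    lumen: np.ndarray
    lipid: np.ndarray
    collagen_in_plaque: np.ndarray
    laminae: LaminaSet
    classmap: ClassMap | None = None

    @property
    def plaque_area_px(self) -> int:
        return int(self.internal.sum()) - int(self.lumen.sum())

    def validate(self) -> None:
        if np.any(self.media & self.internal):
            raise SegmentationError("media and internal overlap")
        for name in ("lumen", "lipid", "collagen_in_plaque"):
            if np.any(getattr(self, name) & ~self.internal):
                raise SegmentationError(f"{name} leaks outside the internal area")
        if np.any(self.lumen & self.lipid):
            raise SegmentationError("lumen and lipid overlap")
        if np.any(self.collagen_in_plaque & self.lumen):
            raise SegmentationError("collagen_in_plaque overlaps the lumen")
        if self.plaque_area_px < 0:
            raise SegmentationError("negative plaque area")

    def area_summary(self) -> dict[str, int]:
        return {
            "media_px": int(self.media.sum()),
            "internal_px": int(self.internal.sum()),
            "lumen_px": int(self.lumen.sum()),
            "plaque_px": self.plaque_area_px,
            "lipid_px": int(self.lipid.sum()),
            "collagen_px": int(self.collagen_in_plaque.sum()),
            "n_laminae": len(self.laminae),
        }


def _mean_thickness(component: np.ndarray) -> float:
    # For a ribbon of width t the Euclidean distance transform averages ~t/4
    # over the ribbon, so 4x the mean distance estimates the local thickness.
    dist = ndi.distance_transform_edt(component)
    return float(4.0 * dist[component].mean())


def detect_laminae(
    elastic_mask: np.ndarray,
    min_enclosed_area: int = 500,
    closing_radius: int = 3,
    max_thickness: float = 25.0,
) -> LaminaSet:
    """Find closed elastic-lamina rings in the purple-threshold mask.

    The purple mask contains not only elastic laminae but also cell nuclei,
    fibrin and foam cells; those are rejected geometrically: after a
    morphological closing (radius ``closing_radius``, bridging small breaks in
    the laminae), only 8-connected components that enclose at least
    ``min_enclosed_area`` pixels of 4-connected interior and are thin
    (mean thickness <= ``max_thickness``) count as laminae.

    Returns the accepted rings ordered by enclosed area ascending; ties broken
    by smaller component pixel count, then by topmost-leftmost centroid.

    Raises
    ------
    NoVesselError
        If no component passes, with component-count diagnostics.
    """
    elastic_mask = np.asarray(elastic_mask, dtype=bool)
    largest_enclosed = 0
    if not elastic_mask.any():
        raise NoVesselError(n_components=0, largest_enclosed_area=0)

    if closing_radius > 0:
        closed = morphological_closing(elastic_mask, disk(closing_radius))
    else:
        closed = elastic_mask
    labels, n_components = cc_label(closed, connectivity=2, return_num=True)

    laminae: list[Lamina] = []
    for idx in range(1, n_components + 1):
        component = labels == idx
        filled = ndi.binary_fill_holes(component)  # default structure: 4-connectivity
        interior = filled & ~component
        enclosed_area = int(interior.sum())
        largest_enclosed = max(largest_enclosed, enclosed_area)
        if enclosed_area < min_enclosed_area:
            continue
        thickness = _mean_thickness(component)
        if thickness > max_thickness:
            continue
        area = int(component.sum())
        perim = float(sk_perimeter(component))
        rows, cols = np.nonzero(component)
        laminae.append(
            Lamina(
                component=component,
                filled=filled,
                interior=interior,
                enclosed_area=enclosed_area,
                mean_thickness=thickness,
                elongation=perim**2 / area if area else 0.0,
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )

    if not laminae:
        raise NoVesselError(n_components=n_components, largest_enclosed_area=largest_enclosed)

    laminae.sort(
        key=lambda lam: (
            lam.enclosed_area,
            int(lam.component.sum()),
            lam.centroid[0],
            lam.centroid[1],
        )
    )
    lamina_set = LaminaSet(laminae=laminae)
    inner, outer = lamina_set.innermost, lamina_set.outermost
    if len(lamina_set) > 1 and np.any(inner.filled & ~outer.filled):
        raise SegmentationError(
            "innermost lamina is not nested inside the outermost; "
            "multi-vessel fields are not supported"
        )
    return lamina_set


def build_media_mask(laminae: LaminaSet, allow_single: bool = False) -> np.ndarray:
    """Vessel media: between the innermost and outermost elastic lamina.

    The filled interior of the outermost lamina (ring included) minus the
    strict interior of the innermost; the inner ring's own pixels belong to
    the media.  With a single detected lamina the media cannot be delimited;
    ``allow_single`` opts into the degenerate zero-width fallback (the ring
    pixels themselves).
    """
    if len(laminae) < 2 and not allow_single:
        raise SegmentationError(
            "cannot delimit media: only one elastic lamina detected "
            "(pass allow_single=True for the zero-width fallback)"
        )
    return laminae.outermost.filled & ~laminae.innermost.interior


def internal_region(laminae: LaminaSet) -> np.ndarray:
    """Internal vessel area: the strict interior of the innermost lamina.

    Occupied by plaque and lumen; disjoint from the media by construction
    (ring pixels excluded).
    """
    return laminae.innermost.interior.copy()


def split_lumen_lipid(
    internal: np.ndarray,
    white_mask: np.ndarray,
    erythrocyte_mask: np.ndarray,
    min_rbc_pixels: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the white areas inside the vessel into lumen and lipid.

    Both lumen and dissolved-lipid areas appear white; the presence of
    yellow-stained erythrocytes identifies the lumen.  Candidate regions are
    8-connected components of ``(white | erythrocyte) & internal``.  A
    component is lumen if it contains white pixels and at least
    ``min_rbc_pixels`` erythrocyte pixels (the erythrocyte pixels are part of
    the lumen); other white-containing components are lipid.  Components made
    of erythrocytes alone (entrapped intraplaque red blood cells) belong to
    neither — the lumen rule keys on white-component membership, not on
    erythrocytes alone.
    """
    if min_rbc_pixels < 1:
        raise ValueError("min_rbc_pixels must be >= 1")
    internal = np.asarray(internal, dtype=bool)
    white_mask = np.asarray(white_mask, dtype=bool)
    erythrocyte_mask = np.asarray(erythrocyte_mask, dtype=bool)
    if not (internal.shape == white_mask.shape == erythrocyte_mask.shape):
        raise ValueError("masks must share dimensions")

    candidates = (white_mask | erythrocyte_mask) & internal
    labels, n = cc_label(candidates, connectivity=2, return_num=True)
    lumen = np.zeros_like(internal)
    lipid = np.zeros_like(internal)
    for idx in range(1, n + 1):
        component = labels == idx
        n_white = int((component & white_mask).sum())
        n_rbc = int((component & erythrocyte_mask).sum())
        if n_white > 0 and n_rbc >= min_rbc_pixels:
            lumen |= component
        elif n_white > 0:
            lipid |= component
    if not lumen.any():
        logger.warning(
            "no erythrocyte-bearing white area found: empty lumen "
            "(the section may graze the vessel)"
        )
    return lumen, lipid


def plaque_pixels(internal: np.ndarray, lumen: np.ndarray) -> int:
    """Plaque area by subtraction: internal vessel area minus lumen area."""
    internal = np.asarray(internal, dtype=bool)
    lumen = np.asarray(lumen, dtype=bool)
    if np.any(lumen & ~internal):
        raise SegmentationError("lumen is not contained in the internal area")
    return int(internal.sum()) - int(lumen.sum())


def collagen_in_plaque(
    blue_mask: np.ndarray, internal: np.ndarray, lumen: np.ndarray
) -> np.ndarray:
    """Collagen inside the plaque: blue-thresholded pixels in internal minus lumen."""
    blue_mask = np.asarray(blue_mask, dtype=bool)
    internal = np.asarray(internal, dtype=bool)
    lumen = np.asarray(lumen, dtype=bool)
    if not (blue_mask.shape == internal.shape == lumen.shape):
        raise ValueError("masks must share dimensions")
    return blue_mask & internal & ~lumen


def segment_section(
    image: np.ndarray,
    config: ColorConfig | None = None,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Run the full segmentation pipeline on one RGB micrograph.

    Composes pixel classification, lamina detection, media/internal
    construction, the lumen/lipid split and intraplaque collagen masking, and
    verifies the mask algebra before returning.
    """
    if params is None:
        params = SegmentationParams()
    classmap = classify_pixels(image, config)
    purple = class_mask(classmap, StainClass.ELASTIC_PURPLE)
    laminae = detect_laminae(
        purple,
        min_enclosed_area=params.min_enclosed_area,
        closing_radius=params.closing_radius,
        max_thickness=params.max_thickness,
    )
    media = build_media_mask(laminae, allow_single=params.allow_single_lamina)
    internal = internal_region(laminae)
    lumen, lipid = split_lumen_lipid(
        internal,
        class_mask(classmap, StainClass.WHITE),
        class_mask(classmap, StainClass.ERYTHROCYTE_YELLOW),
        min_rbc_pixels=params.min_rbc_pixels,
    )
    collagen = collagen_in_plaque(
        class_mask(classmap, StainClass.COLLAGEN_BLUE), internal, lumen
    )
    result = SegmentationResult(
        media=media,
        internal=internal,
        lumen=lumen,
        lipid=lipid,
        collagen_in_plaque=collagen,
        laminae=laminae,
        classmap=classmap,
    )
    result.validate()
    return result
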