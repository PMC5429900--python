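"""Synthetic OMSB-like artery cross-sections with exact ground truth.

No image data accompanies the original morphometry workflow, so every
pipeline stage is exercised against generated sections whose per-compartment
masks and areas are known exactly.  A section is a set of concentric elastic
laminae (purple rings, optionally broken), a pink media between them, an
internal area split into an eccentric white lumen seeded with yellow
erythrocyte disks and a pink/red plaque matrix carrying blue collagen blobs,
white lipid vacuoles and small purple nuclei (the blobs the lamina detector
must reject).  Background outside the vessel is white, as on a slide.

Ground truth is recorded from the analytic geometry before breaks and noise
are applied, so recovered areas can be scored against exact references.
Noise is additive Gaussian per channel, clipped to [0, 255] — the simplest
stand-in for stain and illumination variability.  All randomness flows from
one seed through numpy's SeedSequence so cohort- and section-level
reproducibility are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

# Prototype stain colors (RGB).  Chosen to sit centrally in the default hue
# sectors of the color model: purple ~290 deg, blue ~225 deg, yellow ~50 deg,
# pink ~349 deg.
COLOR_BACKGROUND = (250, 250, 250)
COLOR_PURPLE = (140, 40, 180)
COLOR_BLUE = (40, 80, 200)
COLOR_YELLOW = (230, 200, 40)
COLOR_PINK = (230, 120, 140)
COLOR_RED = (210, 60, 80)
COLOR_WHITE = (250, 250, 250)


class SectionSpecError(ValueError):
    pass


@dataclass
class SectionSpec:
    """Geometry and appearance of one synthetic section.

    ``lamina_radii`` lists ``(inner, outer)`` pixel radii per lamina,
    strictly nested and non-overlapping, innermost first.  ``plaque_fraction``
    is the fraction of the internal area occupied by plaque (the lumen radius
    is derived as ``r_internal * sqrt(1 - plaque_fraction)``), and
    ``lumen_offset_frac`` displaces the lumen center by that fraction of the
    internal radius, producing a crescent-shaped plaque.
    """

    shape: tuple[int, int] = (288, 288)
    center: tuple[float, float] | None = None  # (row, col); default image center
    lamina_radii: tuple[tuple[float, float], ...] = ((100.0, 104.0), (120.0, 124.0))
    lamina_break_arcs: tuple[tuple[float, float] | None, ...] | None = None  # (start_deg, extent_deg)
    plaque_fraction: float = 0.85
    lumen_offset_frac: float = 0.25
    collagen_blobs: int = 12
    collagen_radius: tuple[float, float] = (7.0, 12.0)
    lipid_vacuoles: int = 8
    lipid_radius: tuple[float, float] = (8.0, 14.0)
    n_erythrocytes: int = 25
    erythrocyte_radius: float = 2.0
    entrapped_erythrocytes: int = 0
    n_nuclei: int = 40
    nuclei_radius: tuple[float, float] = (1.0, 2.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.lamina_radii) < 1:
            raise SectionSpecError("need at least one lamina")
        prev_outer = 0.0
        for inner, outer in self.lamina_radii:
            if not 0 < inner < outer:
                raise SectionSpecError(f"malformed lamina radii ({inner}, {outer})")
            if inner <= prev_outer:
                raise SectionSpecError("lamina radii must be strictly nested and non-overlapping")
            prev_outer = outer
        if self.lamina_break_arcs is not None:
            if len(self.lamina_break_arcs) != len(self.lamina_radii):
                raise SectionSpecError("one break arc entry per lamina (None for unbroken)")
            for arc in self.lamina_break_arcs:
                if arc is not None and not 0 <= arc[1] < 360:
                    raise SectionSpecError("break arcs must span less than 360 degrees")
        if not 0.0 <= self.plaque_fraction < 1.0:
            raise SectionSpecError("plaque_fraction must lie in [0, 1)")
        for name in ("collagen_blobs", "lipid_vacuoles", "n_erythrocytes",
                     "entrapped_erythrocytes", "n_nuclei"):
            if getattr(self, name) < 0:
                raise SectionSpecError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise SectionSpecError("noise_sigma must be >= 0")

    @property
    def center_rc(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


@dataclass
class SyntheticGroundTruth:
    """Exact masks and pixel areas for a generated section."""

    media: np.ndarray
    internal: np.ndarray
    lumen: np.ndarray
    lipid: np.ndarray
    collagen: np.ndarray
    spec: SectionSpec = field(repr=False)

    @property
    def areas_px(self) -> dict[str, int]:
        internal = int(self.internal.sum())
        lumen = int(self.lumen.sum())
        return {
            "media_px": int(self.media.sum()),
            "internal_px": internal,
            "lumen_px": lumen,
            "plaque_px": internal - lumen,
            "lipid_px": int(self.lipid.sum()),
            "collagen_px": int(self.collagen.sum()),
        }


def _paint_disks(
    canvas: np.ndarray,
    allowed: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    color: tuple[int, int, int],
    painted: np.ndarray,
) -> None:
    """Paint disks onto ``canvas`` clipped to ``allowed``; record in ``painted``."""
    h, w = canvas.shape[:2]
    for (cr, cc), radius in zip(centers, radii):
        r0, r1 = max(0, int(cr - radius - 1)), min(h, int(cr + radius + 2))
        c0, c1 = max(0, int(cc - radius - 1)), min(w, int(cc + radius + 2))
        rr, cc_grid = np.mgrid[r0:r1, c0:c1]
        disk = ((rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2) & allowed[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1][disk] = color
        painted[r0:r1, c0:c1] |= disk


def _sample_in_region(
    rng: np.random.Generator,
    region: np.ndarray,
    n: int,
    margin_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sample n pixel centers uniformly from region (optionally restricted)."""
    candidates = region if margin_mask is None else (region & margin_mask)
    rows, cols = np.nonzero(candidates)
    if rows.size == 0 or n == 0:
        return np.empty((0, 2))
    idx = rng.integers(0, rows.size, size=n)
    return np.stack([rows[idx], cols[idx]], axis=1).astype(float)


def generate_section(spec: SectionSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Deterministic for a fixed ``spec.seed``: the same spec always yields a
    bit-identical image.  Ground truth reflects the analytic geometry before
    lamina breaks and color noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cy, cx = spec.center_rc
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)

    inner_in, inner_out = spec.lamina_radii[0]
    outer_in, outer_out = spec.lamina_radii[-1]
    if outer_out + 2 > min(cy, cx, h - 1 - cy, w - 1 - cx):
        raise SectionSpecError("outermost lamina does not fit inside the image")

    internal = dist < inner_in  # strict interior of the inner lamina
    media = (dist >= inner_in) & (dist <= outer_out)

    # Eccentric lumen inside the internal area.
    r_internal = inner_in
    r_lumen = r_internal * math.sqrt(max(0.0, 1.0 - spec.plaque_fraction))
    max_offset = max(0.0, r_internal - r_lumen - 4.0)  # keep a plaque rim
    offset = min(spec.lumen_offset_frac * r_internal, max_offset)
    theta = rng.uniform(0, 2 * math.pi)
    ly, lx = cy + offset * math.sin(theta), cx + offset * math.cos(theta)
    lumen_dist = np.sqrt((rr - ly) ** 2 + (cc - lx) ** 2)
    lumen = (lumen_dist <= r_lumen) & internal
    plaque = internal & ~lumen

    # --- render ---
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[...] = COLOR_BACKGROUND
    image[media] = COLOR_PINK
    image[plaque] = COLOR_RED
    image[lumen] = COLOR_WHITE

    # Elastic laminae (purple rings), between-laminae media stays pink.
    angle = np.degrees(np.arctan2(rr - cy, cc - cx)) % 360.0
    for k, (r_in, r_out) in enumerate(spec.lamina_radii):
        ring = (dist >= r_in) & (dist <= r_out)
        if spec.lamina_break_arcs is not None and spec.lamina_break_arcs[k] is not None:
            start, extent = spec.lamina_break_arcs[k]
            gap = (angle - start) % 360.0 < extent
            ring = ring & ~gap
        image[ring] = COLOR_PURPLE

    # Keep blobs off the lumen boundary and the inner lamina so white regions
    # stay separable: a 4 px guard ring around the lumen and the lamina.
    guard = (lumen_dist > r_lumen + 4.0) & (dist < inner_in - 4.0)
    plaque_safe = plaque & guard

    collagen_painted = np.zeros((h, w), dtype=bool)
    if spec.collagen_blobs:
        centers = _sample_in_region(rng, plaque_safe, spec.collagen_blobs)
        radii = rng.uniform(*spec.collagen_radius, size=len(centers))
        _paint_disks(image, plaque_safe, centers, radii, COLOR_BLUE, collagen_painted)

    lipid_painted = np.zeros((h, w), dtype=bool)
    if spec.lipid_vacuoles:
        centers = _sample_in_region(rng, plaque_safe, spec.lipid_vacuoles)
        radii = rng.uniform(*spec.lipid_radius, size=len(centers))
        _paint_disks(image, plaque_safe, centers, radii, COLOR_WHITE, lipid_painted)
    collagen_painted &= ~lipid_painted  # vacuoles overwrite collagen

    # Erythrocytes: yellow disks inside the lumen (margin keeps them off the
    # plaque boundary so the lumen component stays a single white+yellow blob).
    rbc_painted = np.zeros((h, w), dtype=bool)
    if spec.n_erythrocytes:
        core = lumen & (lumen_dist <= max(0.0, r_lumen - spec.erythrocyte_radius - 2.0))
        centers = _sample_in_region(rng, core, spec.n_erythrocytes)
        radii = np.full(len(centers), spec.erythrocyte_radius)
        _paint_disks(image, lumen, centers, radii, COLOR_YELLOW, rbc_painted)

    # Entrapped erythrocytes inside the plaque matrix: yellow-only components
    # that must NOT be claimed as lumen.
    if spec.entrapped_erythrocytes:
        matrix = plaque_safe & ~collagen_painted & ~lipid_painted
        centers = _sample_in_region(rng, matrix, spec.entrapped_erythrocytes)
        radii = np.full(len(centers), spec.erythrocyte_radius)
        _paint_disks(image, matrix, centers, radii, COLOR_YELLOW, np.zeros((h, w), bool))

    # Cell nuclei: small purple blobs in the plaque matrix that the lamina
    # detector must reject geometrically.
    if spec.n_nuclei:
        matrix = plaque_safe & ~collagen_painted & ~lipid_painted & ~rbc_painted
        centers = _sample_in_region(rng, matrix, spec.n_nuclei)
        radii = rng.uniform(*spec.nuclei_radius, size=len(centers))
        _paint_disks(image, matrix, centers, radii, COLOR_PURPLE, np.zeros((h, w), bool))

    truth = SyntheticGroundTruth(
        media=media,
        internal=internal,
        lumen=lumen,
        lipid=lipid_painted,
        collagen=collagen_painted,
        spec=spec,
    )

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=image.shape)
        image = np.clip(image.astype(np.float64) + noise, 0, 255).round().astype(np.uint8)

    return image, truth


@dataclass
class CohortSection:
    """One member of a generated two-group cohort."""

    index: int
    group: str  # "proximal" | "distal"
    spec: SectionSpec
    truth: SyntheticGroundTruth
    image: np.ndarray | None


def _draw_spec(rng: np.random.Generator, base: SectionSpec, effects: dict[str, float]) -> SectionSpec:
    """Draw one section's geometry from the cohort distributions."""
    vessel_scale = effects.get("vessel", 1.0)
    r_in = float(np.clip(rng.normal(100.0, 8.0), 75.0, 118.0)) * vessel_scale
    lam_thick = rng.uniform(3.5, 5.0)
    media_ratio = float(np.clip(rng.normal(0.5, 0.06), 0.3, 0.75))
    r_media_out = r_in * math.sqrt(1.0 + media_ratio)
    plaque_frac = float(np.clip(rng.normal(0.70, 0.04) * effects.get("plaque", 1.0), 0.05, 0.95))
    # Canvas sized to the drawn vessel so extreme draws always fit.
    required = int(2 * (r_media_out + lam_thick + 8)) + 1
    shape = (max(base.shape[0], required), max(base.shape[1], required))
    return replace(
        base,
        shape=shape,
        center=None,
        lamina_radii=(
            (r_in, r_in + lam_thick),
            (r_media_out, r_media_out + lam_thick),
        ),
        plaque_fraction=plaque_frac,
        lumen_offset_frac=rng.uniform(0.0, 0.35),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_per_group: int,
    group_effects: dict[str, float] | None = None,
    seed: int = 0,
    render: bool = True,
    base_spec: SectionSpec | None = None,
) -> Iterator[CohortSection]:
    """Generate a proximal-like and a distal-like group of sections.

    Per-section geometry (internal radius, media thickness, plaque fraction,
    lumen eccentricity) is drawn from documented distributions; the
    distal-like group applies the multiplicative ``group_effects`` (supported
    keys: ``"plaque"`` scales the plaque fraction, ``"vessel"`` scales the
    vessel radius).  Reproducible per ``seed``; with ``render=False`` the
    yielded records carry ground truth only (``image=None``).
    """
    if n_per_group < 1:
        raise SectionSpecError("n_per_group must be >= 1")
    effects = dict(group_effects or {})
    if base_spec is None:
        base_spec = SectionSpec()
    ss = np.random.SeedSequence(seed)
    group_seqs = ss.spawn(2)
    index = 0
    for group, gseq, geffects in (
        ("proximal", group_seqs[0], {}),
        ("distal", group_seqs[1], effects),
    ):
        rng = np.random.default_rng(gseq)
        for _ in range(n_per_group):
            spec = _draw_spec(rng, base_spec, geffects)
            image, truth = generate_section(spec)
            yield CohortSection(
                index=index,
                group=group,
                spec=spec,
                truth=truth,
                image=image if render else None,
            )
            index += 1
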