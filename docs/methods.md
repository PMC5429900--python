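# Methods

## Segmentation model

The pipeline assumes a single artery cross-section per image, stained with
the OMSB polychrome so that tissue classes are hue-separated: elastic fibers
purple, collagen blue, erythrocytes yellow, muscle/fibrin/nuclei red-pink,
and unstained (lumen, dissolved lipid, slide background) white.  It further
assumes the vessel wall presents at least two concentric elastic laminae
whose rings close — possibly after bridging small breaks — and that the inner
lamina separates the wall from the internal area holding plaque and lumen.

### Color model

Classification is per-pixel in HSV.  WHITE is decided first (value ≥ 0.85,
saturation ≤ 0.15): at low saturation hue is numerically unstable, so testing
chromatic classes first would hand bright desaturated pixels spurious hue
labels.  Chromatic classes then claim half-open hue sectors (yellow 40–70°,
blue 190–260°, purple 260–320°, red-pink 320–40° wrapping); leftover hues
(greens, cyans) become OTHER.  The default sectors are conventions for the
named stain colors, not measured dye spectra; they are deliberately wide so
that moderate stain variability and additive noise (σ ≈ 8 intensity levels)
move almost no pixel across a sector boundary.  All thresholds are exposed in
one YAML config.  No attempt is made to separate nuclei/fibrin/foam cells
from elastic fibers by color — they share the purple label and are removed
geometrically downstream.

### Lamina detection

The purple mask is closed with a disk (default radius 3 px) to bridge broken
laminae; 8-connected components are then tested as rings: the 4-connected
hole fill of a component defines its strict interior, and a component is an
elastic lamina if that interior is at least `min_enclosed_area` (default
500 px) and the component is thin — mean thickness, estimated as 4× the mean
Euclidean distance transform over the component (a ribbon of width *t*
averages *t*/4), at most `max_thickness` (default 25 px).  Compact blobs
(nuclei, foam-cell clusters) fail the ring test; thick solid regions fail the
thickness test.  Texture is thus approximated purely geometrically (thin,
closed, enclosing); this is a stated surrogate, not a reproduction of any
particular texture descriptor.  The complementary 8/4 connectivity pair for
foreground/background is the standard choice preventing a ring from being
simultaneously closed and leaky.  A convex-hull fallback for closure was
considered and rejected: it destroys the ring/interior distinction for
crescent-shaped laminae.

Rings are ordered by enclosed area, ties broken by component pixel count,
then by topmost-leftmost centroid — a total, deterministic order.  The
innermost ring's pixels are assigned to the media, not the internal area: a
boundary outlines a region without belonging to it, and this convention makes
media and internal exactly disjoint.  If only one ring is found the media is
undeliverable; callers may opt into a zero-width fallback
(`allow_single_lamina`) for grazing sections.

### Lumen vs lipid

Both appear white; erythrocytes identify the lumen.  Candidate regions are
connected components of (white ∪ yellow) ∩ internal.  A component is lumen
iff it contains white pixels **and** at least `min_rbc_pixels` yellow pixels;
white components without enough erythrocytes are lipid; yellow-only
components (erythrocytes entrapped in plaque tissue) are neither — the rule
keys on white-component membership so intraplaque red blood cells cannot
masquerade as lumen.  `min_rbc_pixels` defaults to 10 px at 0.5 μm/px and
scales with (0.5/calibration)², since the pixel footprint of one erythrocyte
grows quadratically with resolution.  An erythrocyte-free section yields an
empty lumen with a logged warning rather than an error.

Plaque is never masked directly: it is the arithmetic difference
internal − lumen, so any mask error in lumen propagates one-for-one — the
validation suite therefore scores plaque recovery explicitly.  Lipid is
restricted to the internal area; white background outside the outer lamina is
never lipid.

## Morphometry

Pixel counts × (μm/px)² give absolute areas; total vessel area is exactly
media + lumen + plaque, relative lumen/plaque/media are fractions of the
total, relative collagen/lipid are fractions of the plaque area.  Ratios with
zero denominators are explicitly `None` (undefined), never 0 — a plaque-free
section must not report 0% collagen.  All arithmetic is double precision;
two-decimal output is rendering only.  Published per-section legends mix
truncation and rounding at the second decimal, so reproduction of printed
values is asserted to 0.02 percentage points rather than to a guessed
rounding rule.

## Group statistics

The Mann–Whitney U statistic is computed from midranks (U for group 1;
swapping groups maps U ↦ n₁n₂ − U).  With n₁ + n₂ ≤ 12 and no ties the
two-sided p is exact, by enumerating all C(n₁+n₂, n₁) rank assignments and
doubling the lower tail of min(U, n₁n₂ − U) (capped at 1); otherwise the
normal approximation with tie correction and a 0.5 continuity correction is
used.  The exact branch is verified against an independent pairwise-count
permutation oracle for every split with n₁ + n₂ ≤ 10, and the approximate
branch's type-I error at α = 0.05 is checked by simulation to lie in
[0.03, 0.07] at n = 150/150.  The implementation is in-package (not
delegated) precisely so both branches are testable against such oracles.

Quartiles use the (n+1)p linear-interpolation convention, matching both the
convention of widely used biostatistics software and hand-computable box
examples (for {1..7}: Q1 = 2, Q3 = 6); whiskers sit at the most extreme data
points within 1.5 × IQR of the quartiles, points beyond are outliers.  The
ten parameters (six absolute areas, four relative) are each tested marginally
at α = 0.05 with no multiplicity correction, mirroring standard practice in
this assay; Holm adjustment is available behind a flag.

## Synthetic sections

The generator emulates what the segmentation relies on, not histology per
se: concentric purple rings (default inner lamina at 100–104 px, outer at
120–124 px on a 288² canvas — at 0.5 μm/px a ~100 μm-radius vessel), pink
media, an eccentric white lumen (area fraction of the internal disk set by
`plaque_fraction`, default 0.85 to resemble an advanced lesion), a red
plaque matrix with blue collagen blobs and white lipid vacuoles, yellow
erythrocyte disks in the lumen, optional entrapped erythrocytes in the
plaque, purple nuclei blobs for the detector to reject, optional angular
lamina breaks, and additive Gaussian RGB noise clipped to [0, 255].  Ground
truth is recorded from the analytic geometry before breaks and noise.  Blobs
keep a 4 px guard band off the lumen and the inner lamina so that white
components remain topologically separable — real sections do not offer that
guarantee, which is one reason synthetic recovery (≤ ~1% error) is better
than what slides would show.

Not emulated: stain chemistry and spectral overlap, illumination gradients,
fibrous caps, pseudochondroplasia, fibrin age classes, sectioning artifacts,
touching vessels.  Passing recovery tests therefore demonstrates the
correctness of the mask algebra and the robustness of the geometric rules to
pixel noise and broken rings — not performance on real slides, which depends
on threshold tuning per staining batch.

Cohorts draw per-section geometry from documented distributions (internal
radius ~N(100, 8) px clipped to [75, 118], media/internal area ratio
~N(0.5, 0.06), plaque fraction ~N(0.70, 0.04)); the cohort baseline plaque
fraction sits lower than the single-section default so that a +20%
multiplicative "distal" effect stays inside the feasible (0, 0.95) range
without clipping distorting the realized effect size.  One seed drives
everything through `numpy.random.SeedSequence` spawning, so cohort-level and
section-level reproducibility are independent.

## Problem sizes used in validation

Recovery is validated on 20 noise-free and 5 noisy (σ = 8) sections; the
null calibration of the U test uses 1,000 replicates at n = 150 per group;
the cohort power check uses 150 sections per group (ground-truth areas, no
rendering) — matching the scale of a typical serial-sectioning study.  The
law-of-large-numbers check of the generated effect size uses 400 sections
per group.

## Known limitations

- Thresholds are defaults for the synthetic colors and named hue sectors;
  real batches require calibration of the YAML config against a few slides.
- One vessel per image; no serial-section registration; no sub-plaque lesion
  typing (caps, pseudochondroplasia, fibrin age).
- Media detection requires two closed laminae (after closing); heavily
  fragmented laminae beyond the closing radius yield a "no vessel" error
  rather than a partial result.
- The lumen rule needs erythrocytes; a flushed, blood-free lumen is
  classified as lipid — flagged only by the empty-lumen warning.
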