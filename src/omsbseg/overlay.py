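"""Pseudocolor overlays for visual inspection of a segmentation.

The conventional palette: vessel media red, lumen green, intraplaque collagen
blue and lipids yellow, blended semi-transparently over the original image so
segmentation adequacy can be judged against the underlying histology.
"""

from __future__ import annotations

import numpy as np

OVERLAY_COLORS = {
    "media": (255, 0, 0),
    "lumen": (0, 255, 0),
    "collagen_in_plaque": (0, 0, 255),
    "lipid": (255, 255, 0),
}


def render_overlay(image: np.ndarray, seg, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend the pseudocolored compartment masks over the micrograph.

    ``out = (1 - alpha) * image + alpha * color`` on each mask; masks are
    applied media, lumen, collagen, lipid (later masks win where they overlap,
    though the mask algebra keeps them disjoint).  ``alpha=0`` or empty masks
    reproduce the input exactly.
    """
    image = np.asarray(image)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    out = image.astype(np.float64)
    for name, color in OVERLAY_COLORS.items():
        mask = np.asarray(getattr(seg, name), bool)
        if mask.shape != image.shape[:2]:
            raise ValueError(f"mask {name} shape {mask.shape} != image {image.shape[:2]}")
        out[mask] = (1.0 - alpha) * out[mask] + alpha * np.asarray(color, np.float64)
    return np.clip(out.round(), 0, 255).astype(np.uint8)
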