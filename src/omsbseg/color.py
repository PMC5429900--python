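"""Per-pixel stain-class classification for OMSB-stained sections.

The OMSB polychrome stain separates tissue components by hue: orcein colors
elastic fibers purple, methyl blue colors collagen blue, martius yellow colors
erythrocytes yellow, and crystal scarlet colors muscle, fibrin and nuclei
red/pink; lumen and dissolved-lipid areas are unstained (white).  Because the
classes are hue-separated, classification happens in HSV space: WHITE is
decided first from brightness and saturation (hue is meaningless at low
saturation), then each chromatic class claims a hue sector, and anything left
is OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from skimage.color import rgb2hsv


class StainClass(IntEnum):
    """Stain classes produced by :func:`classify_pixels`."""

    OTHER = 0
    ELASTIC_PURPLE = 1
    COLLAGEN_BLUE = 2
    ERYTHROCYTE_YELLOW = 3
    RED_PINK = 4
    WHITE = 5


#: Chromatic classes that carry a hue range in :class:`ColorConfig`.
CHROMATIC_CLASSES = (
    StainClass.ELASTIC_PURPLE,
    StainClass.COLLAGEN_BLUE,
    StainClass.ERYTHROCYTE_YELLOW,
    StainClass.RED_PINK,
)


class ColorConfigError(ValueError):
    """Raised for malformed color-threshold configurations."""


def _default_hue_ranges() -> dict[StainClass, tuple[float, float]]:
    # Hue sectors in degrees; a range with low > high wraps through 0/360.
    return {
        StainClass.ERYTHROCYTE_YELLOW: (40.0, 70.0),
        StainClass.COLLAGEN_BLUE: (190.0, 260.0),
        StainClass.ELASTIC_PURPLE: (260.0, 320.0),
        StainClass.RED_PINK: (320.0, 40.0),
    }


@dataclass
class ColorConfig:
    """Hue/saturation/value thresholds defining the stain classes.

    Parameters
    ----------
    hue_ranges
        Per-class ``(low, high)`` hue sector in degrees.  Half-open
        ``[low, high)``; ``low > high`` wraps modulo 360.
    white_min_value
        Brightness floor (fraction of full scale) for WHITE.
    white_max_saturation
        Saturation ceiling for WHITE.
    priority
        Order in which chromatic classes claim pixels when user-supplied hue
        sectors overlap.  WHITE is always tested first.
    """

    hue_ranges: dict[StainClass, tuple[float, float]] = field(
        default_factory=_default_hue_ranges
    )
    white_min_value: float = 0.85
    white_max_saturation: float = 0.15
    priority: tuple[StainClass, ...] = CHROMATIC_CLASSES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.white_min_value <= 1.0:
            raise ColorConfigError("white_min_value must be in [0, 1]")
        if not 0.0 <= self.white_max_saturation <= 1.0:
            raise ColorConfigError("white_max_saturation must be in [0, 1]")
        for cls in self.priority:
            if cls not in self.hue_ranges:
                raise ColorConfigError(f"missing hue range for {cls.name}")
        for cls, (lo, hi) in self.hue_ranges.items():
            if not (0.0 <= lo <= 360.0 and 0.0 <= hi <= 360.0):
                raise ColorConfigError(
                    f"hue range for {cls.name} must lie in [0, 360], got {(lo, hi)}"
                )
        if len(set(self.priority)) != len(self.priority):
            raise ColorConfigError("priority lists a class twice")

    def to_dict(self) -> dict:
        return {
            "white_min_value": self.white_min_value,
            "white_max_saturation": self.white_max_saturation,
            "hue_ranges": {
                cls.name.lower(): [float(lo), float(hi)]
                for cls, (lo, hi) in self.hue_ranges.items()
            },
            "priority": [cls.name.lower() for cls in self.priority],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ColorConfig":
        kwargs: dict = {}
        if "white_min_value" in data:
            kwargs["white_min_value"] = float(data["white_min_value"])
        if "white_max_saturation" in data:
            kwargs["white_max_saturation"] = float(data["white_max_saturation"])
        if "hue_ranges" in data:
            ranges = {}
            for name, (lo, hi) in data["hue_ranges"].items():
                ranges[StainClass[name.upper()]] = (float(lo), float(hi))
            kwargs["hue_ranges"] = ranges
        if "priority" in data:
            kwargs["priority"] = tuple(
                StainClass[name.upper()] for name in data["priority"]
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel stain labels; same shape as the source image."""

    labels: np.ndarray  # uint8 array of StainClass values, shape (H, W)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def counts(self) -> dict[StainClass, int]:
        """Pixel count per class; counts sum to H*W (label partition)."""
        binned = np.bincount(self.labels.ravel(), minlength=len(StainClass))
        return {cls: int(binned[cls]) for cls in StainClass}


def _hue_in_range(hue_deg: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg < hi)
    return (hue_deg >= lo) | (hue_deg < hi)  # wraps through 0/360


def classify_pixels(image: np.ndarray, config: ColorConfig | None = None) -> ClassMap:
    """Classify every pixel of an 8-bit RGB image into a stain class.

    Purely per-pixel (no spatial context) and deterministic.  WHITE is tested
    first, then chromatic classes in ``config.priority`` order; unclaimed
    pixels become OTHER.

    Parameters
    ----------
    image
        ``(H, W, 3)`` uint8 RGB array.
    config
        Thresholds; defaults to :class:`ColorConfig` defaults.
    """
    if config is None:
        config = ColorConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit per channel (uint8), got {image.dtype}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must be non-empty")

    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    labels = np.full(image.shape[:2], StainClass.OTHER, dtype=np.uint8)
    unclaimed = np.ones(image.shape[:2], dtype=bool)

    white = (val >= config.white_min_value) & (sat <= config.white_max_saturation)
    labels[white] = StainClass.WHITE
    unclaimed &= ~white

    for cls in config.priority:
        lo, hi = config.hue_ranges[cls]
        sel = unclaimed & _hue_in_range(hue, lo, hi)
        labels[sel] = cls
        unclaimed &= ~sel

    return ClassMap(labels=labels)


def class_mask(classmap: ClassMap, label: StainClass) -> np.ndarray:
    """Boolean mask of pixels carrying ``label``."""
    label = StainClass(label)  # raises ValueError for unknown labels
    return classmap.labels == label
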