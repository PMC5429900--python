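"""One plain-text (YAML) configuration for thresholds and parameters.

A single file carries the color thresholds, the geometric segmentation
parameters and the spatial calibration; every run echoes the fully resolved
configuration next to its outputs so results stay attributable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .color import ColorConfig
from .morphometry import Calibration
from .segmentation import SegmentationParams


@dataclass
class RunConfig:
    color: ColorConfig = field(default_factory=ColorConfig)
    params: SegmentationParams = field(default_factory=SegmentationParams)
    calibration: Calibration = field(default_factory=lambda: Calibration(0.5))

    def to_dict(self) -> dict:
        return {
            "calibration": {"microns_per_pixel": self.calibration.microns_per_pixel},
            "color": self.color.to_dict(),
            "segmentation": {
                "min_enclosed_area": self.params.min_enclosed_area,
                "closing_radius": self.params.closing_radius,
                "max_thickness": self.params.max_thickness,
                "min_rbc_pixels": self.params.min_rbc_pixels,
                "allow_single_lamina": self.params.allow_single_lamina,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        color = ColorConfig.from_dict(data.get("color", {}))
        seg = data.get("segmentation", {})
        params = SegmentationParams(
            min_enclosed_area=int(seg.get("min_enclosed_area", 500)),
            closing_radius=int(seg.get("closing_radius", 3)),
            max_thickness=float(seg.get("max_thickness", 25.0)),
            min_rbc_pixels=int(seg.get("min_rbc_pixels", 10)),
            allow_single_lamina=bool(seg.get("allow_single_lamina", False)),
        )
        cal = Calibration(float(data.get("calibration", {}).get("microns_per_pixel", 0.5)))
        return cls(color=color, params=params, calibration=cal)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
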