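"""Reading micrographs, writing masks/overlays, tabulating records."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometry import MorphometryRecord

MORPHOMETRY_COLUMNS = [
    "section_id",
    "segment_label",
    "media_area",
    "lumen_area",
    "plaque_area",
    "collagen_area",
    "lipid_area",
    "total_vessel_area",
    "relative_media",
    "relative_lumen",
    "relative_plaque",
    "relative_collagen",
    "relative_lipid",
]


def read_rgb_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG micrograph as an (H, W, 3) uint8 array.

    Grayscale images are replicated to three channels; an alpha channel, if
    present, is dropped.  Only 8-bit-per-channel input is accepted.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit per channel, got {arr.dtype}")
    return np.ascontiguousarray(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8)) * 255)


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def mask_to_rle(mask: np.ndarray) -> str:
    """Run-length encode a binary mask as plain text.

    Format: ``H W`` on the first line, then alternating run lengths of 0s and
    1s in row-major order, starting with zeros.
    """
    mask = np.asarray(mask, bool)
    flat = mask.ravel()
    h, w = mask.shape
    if flat.size == 0:
        return f"{h} {w}\n"
    boundaries = np.flatnonzero(np.diff(flat.view(np.int8))) + 1
    starts = np.concatenate([[0], boundaries, [flat.size]])
    runs = np.diff(starts).tolist()
    if flat[0]:  # convention: first run counts zeros
        runs = [0] + runs
    return f"{h} {w}\n" + " ".join(str(r) for r in runs) + "\n"


def rle_to_mask(text: str) -> np.ndarray:
    lines = text.strip().splitlines()
    h, w = (int(v) for v in lines[0].split())
    runs = [int(v) for v in lines[1].split()] if len(lines) > 1 else []
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != h * w:
        raise ValueError("run lengths do not cover the mask")
    return flat.reshape(h, w)


def segmentation_summary_json(seg, path: str | Path | None = None) -> str:
    """Serialize a SegmentationResult's area summary to JSON."""
    payload = seg.area_summary()
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def records_to_dataframe(records: list[MorphometryRecord]) -> pd.DataFrame:
    rows = [r.to_dict() for r in records]
    df = pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)
    return df


def write_morphometry_csv(records: list[MorphometryRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_morphometry_csv(path: str | Path) -> list[MorphometryRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in MORPHOMETRY_COLUMNS:
            value = row.get(col)
            if col in ("section_id", "segment_label"):
                kwargs[col] = "" if pd.isna(value) else str(value)
            else:
                kwargs[col] = None if pd.isna(value) else float(value)
        records.append(MorphometryRecord(**kwargs))
    return records


def comparison_to_dataframe(results) -> pd.DataFrame:
    """Flatten GroupComparisonResults into one row per parameter."""
    rows = []
    for r in results:
        row = {
            "parameter": r.parameter_name,
            "n_group1": r.n_group1,
            "n_group2": r.n_group2,
            "u_statistic": r.u_statistic,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for tag, box in (("g1", r.box_group1), ("g2", r.box_group2)):
            row.update(
                {
                    f"{tag}_median": box.median,
                    f"{tag}_q1": box.q1,
                    f"{tag}_q3": box.q3,
                    f"{tag}_whisker_low": box.whisker_low,
                    f"{tag}_whisker_high": box.whisker_high,
                    f"{tag}_n_outliers": len(box.outliers),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
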