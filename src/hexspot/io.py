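"""Reading and writing 16-bit grayscale TIFFs and spot/quality tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .localize import SpotRecord

SPOT_CSV_COLUMNS = [
    "spot_id", "parity", "line", "col", "x", "y", "a", "b",
    "x0", "y0", "x1", "y1", "missing",
    "fg_mean", "bg_mean", "intensity", "r2", "cv", "n_fg", "n_bg",
]


def read_tiff16(path) -> np.ndarray:
    """Read a single-channel grayscale TIFF as float64.

    Values outside ``[0, 2**16 - 1]`` or multi-channel data are rejected.
    """
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected single-channel 2D TIFF, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("TIFF contains non-finite values")
    if arr.min() < 0 or arr.max() > 2 ** 16 - 1:
        raise InvalidInputError("pixel values outside the 16-bit range [0, 65535]")
    return arr


def write_tiff16(path, pixels: np.ndarray) -> None:
    """Write an array as 16-bit grayscale TIFF (values clipped/rounded)."""
    arr = np.clip(np.rint(np.asarray(pixels, dtype=np.float64)), 0, 2 ** 16 - 1)
    tifffile.imwrite(path, arr.astype(np.uint16))


def spots_to_frame(records: list[SpotRecord]) -> pd.DataFrame:
    """Flatten spot records into the canonical spot table."""
    rows = []
    for i, rec in enumerate(records, start=1):
        x0, y0, x1, y1 = rec.area
        rows.append(
            {
                "spot_id": i,
                "parity": rec.parity,
                "line": rec.line,
                "col": rec.col,
                "x": rec.center[0],
                "y": rec.center[1],
                "a": rec.radii[0],
                "b": rec.radii[1],
                "x0": x0, "y0": y0, "x1": x1, "y1": y1,
                "missing": bool(rec.missing),
                "fg_mean": rec.fg_mean,
                "bg_mean": rec.bg_mean,
                "intensity": rec.intensity,
                "r2": rec.r2,
                "cv": rec.cv,
                "n_fg": int(rec.fg_mask.sum()) if rec.fg_mask is not None else 0,
                "n_bg": int(rec.bg_mask.sum()) if rec.bg_mask is not None else 0,
            }
        )
    return pd.DataFrame(rows, columns=SPOT_CSV_COLUMNS)


def read_spots_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"line", "col", "x", "y", "missing"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"spot table must contain columns {sorted(required)}")
    return table


def write_quality_csv(path, report: dict) -> None:
    """Write a quality report as a flat ``key,value`` CSV."""
    pd.DataFrame(
        {"key": list(report.keys()), "value": list(report.values())}
    ).to_csv(path, index=False)
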