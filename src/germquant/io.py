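"""Calibrated image containers and table I/O.

Conventions used by every table writer in the package: comma-separated
UTF-8 CSV with a mandatory header row, '.' decimal separator, floats at 9
significant digits (lossless well beyond the documented 6), pixel indices
0-based, centroids in μm computed as ``(index + 0.5) * pixel_size``, and the
time of frame ``k`` equal to ``k * frame_interval_min`` (frame 0 = time 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "LabelStack",
    "MEASUREMENT_COLUMNS",
    "read_image_stack",
    "write_image_stack",
    "validate_measurements",
    "write_measurements",
    "read_measurements",
    "write_manifest",
]

#: Fixed column order of a measurement table (long format, one row per
#: object per frame).
MEASUREMENT_COLUMNS = [
    "frame",
    "label",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "major_um",
    "minor_um",
    "aspect_ratio",
    "orientation_rad",
]

_FLOAT_FORMAT = "%.9g"


@dataclass
class ImageStack:
    """A T x H x W (x C) intensity stack with physical calibration.

    ``frames`` has shape (T, H, W) for single-channel data or (T, C, H, W)
    for multi-channel data, with channels named in ``channel_names``.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channel_names: list[str] = field(default_factory=lambda: ["transmitted"])

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(f"frames must be T x H x W (x C), got shape {self.frames.shape}")
        if min(self.frames.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")
        if np.issubdtype(self.frames.dtype, np.floating) and np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.frames.ndim == 4 and len(self.channel_names) != self.frames.shape[1]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[1]

    def channel(self, index: int) -> np.ndarray:
        """Return the (T, H, W) array of one channel."""
        if self.frames.ndim == 3:
            if index != 0:
                raise IndexError("single-channel stack")
            return self.frames
        return self.frames[:, index]

    def frame_time_min(self, frame: int) -> float:
        return frame * self.frame_interval_min


@dataclass
class LabelStack:
    """Per-frame integer label masks; 0 is background."""

    labels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be T x H x W, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def read_image_stack(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_min: float,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a multi-page (optionally multi-channel) TIFF in acquisition order.

    A 3-D array is interpreted as (T, H, W); a 4-D array as (T, C, H, W),
    the layout this package writes.  Raises on unreadable or truncated files
    without returning a partial stack.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim not in (3, 4):
        raise OSError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    if channel_names is None:
        if arr.ndim == 4:
            channel_names = [f"channel{i}" for i in range(arr.shape[1])]
        else:
            channel_names = ["transmitted"]
    return ImageStack(arr, pixel_size_um, frame_interval_min, channel_names)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")


def validate_measurements(table: pd.DataFrame) -> None:
    """Check the measurement-table invariants; raise ValueError on violation."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing column(s): {missing}")
    if len(table) == 0:
        return
    if (table["area_um2"] <= 0).any():
        raise ValueError("area_um2 must be positive")
    if (table["aspect_ratio"] < 1).any():
        raise ValueError("aspect_ratio must be >= 1")
    if (table["major_um"] < table["minor_um"] - 1e-9).any():
        raise ValueError("major_um must be >= minor_um")


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated measurement table as CSV in the fixed column order."""
    validate_measurements(table)
    out = table[MEASUREMENT_COLUMNS + [c for c in table.columns if c not in MEASUREMENT_COLUMNS]]
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_measurements(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_measurements(table)
    return table


def write_manifest(path: str | Path, **params) -> None:
    """Write a JSON run manifest with sorted keys (byte-stable across runs)."""
    Path(path).write_text(json.dumps(params, sort_keys=True, indent=2, default=str) + "\n")
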