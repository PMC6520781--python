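"""Image and table I/O plus the core raster containers.

Coordinate convention (used by every module): 0-based, ``x`` is the column
index and ``y`` the row index, and the center of pixel ``(x, y)`` sits at
the integer coordinate ``(x, y)``.  All physical distances are expressed in
micrometres; conversion happens through ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CHANNELS",
    "DEFAULT_PIXEL_SIZE_UM",
    "FieldImage",
    "LabelMask",
    "read_field",
    "read_label_mask",
    "write_field",
    "write_label_mask",
    "write_spot_table",
    "read_spot_table",
]

CHANNELS = ("pid", "nuclear_stain", "membrane", "brightfield")

#: μm per pixel for a 40x objective on a common CCD chip (6.5 μm pixels);
#: a user-supplied value always takes precedence.
DEFAULT_PIXEL_SIZE_UM = 0.1625

SPOT_TABLE_COLUMNS = ("field_id", "x_px", "y_px", "intensity")


@dataclass
class FieldImage:
    """One fluorescence channel of one microscopic field.

    Parameters
    ----------
    pixels
        2-D nonnegative intensity grid (stored as float64).
    pixel_size_um
        Physical edge length of one pixel in μm (> 0).
    field_id
        Identifier of the field; carried into spot tables.
    channel
        One of ``{"pid", "nuclear_stain", "membrane", "brightfield"}``.
    white_level
        Saturation value of the acquisition (dtype max for integer TIFFs);
        ``None`` when unknown, e.g. for synthetic floating-point images.
    """

    pixels: np.ndarray
    pixel_size_um: float
    field_id: str = "field0"
    channel: str = "pid"
    white_level: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be >= 0")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Integer-labelled objects (0 = background, k >= 1 = object k)."""

    labels: np.ndarray
    pixel_size_um: float
    kind: str = "nucleus"
    field_id: str = "field0"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if np.issubdtype(labels.dtype, np.floating) and np.all(
                labels == np.round(labels)
            ):
                labels = labels.astype(np.int64)
            else:
                raise ValueError("label values must be integers")
        if labels.ndim != 2 or labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D grid")
        if np.any(labels < 0):
            raise ValueError("labels must be >= 0")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.kind not in ("nucleus", "whole_cell"):
            raise ValueError(f"kind must be 'nucleus' or 'whole_cell', got {self.kind!r}")
        self.labels = labels.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.label_ids.size)

    def border_labels(self) -> np.ndarray:
        """Labels of objects touching the field border."""
        edges = np.concatenate(
            [self.labels[0, :], self.labels[-1, :], self.labels[:, 0], self.labels[:, -1]]
        )
        ids = np.unique(edges)
        return ids[ids > 0]


def _read_plane(path: str | Path, channel_index: int | None) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if channel_index is None:
            raise ValueError(
                f"{path}: multi-sample TIFF; pass channel_index to select a plane"
            )
        # accept either plane-major (c, y, x) or interleaved (y, x, c)
        axis = 0 if arr.shape[0] <= 4 < arr.shape[-1] else -1
        arr = np.take(arr, channel_index, axis=axis)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image, got shape {arr.shape}")
    return arr


def read_field(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel: str = "pid",
    field_id: str | None = None,
    channel_index: int | None = None,
) -> FieldImage:
    """Read a single-plane grayscale TIFF as a :class:`FieldImage`.

    Integer dtypes are widened losslessly to float64.  ``white_level`` is set
    from the on-disk integer dtype so that downstream saturation checks work.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_plane(path, channel_index)
    white = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else None
    return FieldImage(
        pixels=arr,
        pixel_size_um=pixel_size_um,
        field_id=field_id or path.stem,
        channel=channel,
        white_level=white,
    )


def write_field(img: FieldImage, path: str | Path, dtype=np.uint16) -> None:
    """Write a field image as a single-plane TIFF, clipping to the dtype range."""
    info = np.iinfo(dtype)
    data = np.clip(np.round(img.pixels), info.min, info.max).astype(dtype)
    tifffile.imwrite(str(path), data)


def read_label_mask(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    kind: str = "nucleus",
    field_id: str | None = None,
) -> LabelMask:
    """Read an integer-valued single-plane TIFF as a :class:`LabelMask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_plane(path, None)
    if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
        raise ValueError(f"{path}: label mask contains fractional values")
    return LabelMask(
        labels=arr,
        pixel_size_um=pixel_size_um,
        kind=kind,
        field_id=field_id or path.stem,
    )


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the 16-bit range")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def write_spot_table(spots, path: str | Path) -> None:
    """Write detected spots as CSV with header (field_id,x_px,y_px,intensity)."""
    df = spots if isinstance(spots, pd.DataFrame) else spots.to_frame()
    df = df.loc[:, list(SPOT_TABLE_COLUMNS)]
    df.to_csv(path, index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read a spot table CSV; validates header and numeric coordinates."""
    df = pd.read_csv(path)
    if list(df.columns) != list(SPOT_TABLE_COLUMNS):
        raise ValueError(
            f"{path}: expected columns {SPOT_TABLE_COLUMNS}, got {tuple(df.columns)}"
        )
    for col in ("x_px", "y_px", "intensity"):
        if len(df) == 0:
            df[col] = df[col].astype(float)
        elif not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: column {col} is not numeric")
    return df
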