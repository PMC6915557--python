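"""Image and table I/O for the platelet-aggregation pipeline.

Images are single-channel grayscale rasters (8- or 16-bit TIFF or PNG) with a
user-supplied pixel-size calibration in µm/pixel.  Binary masks are stored as
8-bit images with foreground 255 and background 0, which keeps them viewable
in any image tool while round-tripping losslessly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageGrid",
    "BinaryMask",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_table",
]

MASK_PROVENANCES = ("triangle", "manual", "synthetic_truth")


@dataclass
class ImageGrid:
    """A 2D grayscale raster with bit depth and pixel-size metadata.

    Row 0 is the top of the image and column 0 the left edge.  All operations
    in this package treat an ``ImageGrid`` as immutable: they return new
    instances and never write into ``pixels``.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be an integer raster")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = int(self.pixels.min()), int(self.pixels.max())
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {self.max_value}]"
            )

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self, name: str | None = None) -> "ImageGrid":
        return ImageGrid(
            self.pixels.copy(),
            self.bit_depth,
            self.pixel_size_um,
            self.name if name is None else name,
        )


@dataclass
class BinaryMask:
    """Boolean raster where True marks platelet/aggregate foreground."""

    pixels: np.ndarray
    pixel_size_um: float
    provenance: str = "triangle"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be a non-empty 2D raster")
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.provenance not in MASK_PROVENANCES:
            raise ValueError(
                f"provenance must be one of {MASK_PROVENANCES}, got {self.provenance!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


def _bit_depth_of(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ValueError(
        f"unsupported pixel type {dtype}; expected 8- or 16-bit unsigned integers"
    )


def read_image(path: str | os.PathLike, pixel_size_um: float) -> ImageGrid:
    """Read a grayscale 8/16-bit TIFF or PNG as an :class:`ImageGrid`.

    Multi-channel (RGB/RGBA) and floating-point images are rejected: the
    pipeline operates on raw single-channel fluorescence intensities.
    """
    path = Path(path)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: multi-channel image (shape {arr.shape}); "
            "a single-channel grayscale image is required"
        )
    depth = _bit_depth_of(arr.dtype)
    return ImageGrid(arr, depth, pixel_size_um, name=path.stem)


def read_mask(
    path: str | os.PathLike, pixel_size_um: float, provenance: str = "manual"
) -> BinaryMask:
    """Read a stored mask image; any nonzero pixel counts as foreground."""
    grid = read_image(path, pixel_size_um)
    return BinaryMask(grid.pixels > 0, pixel_size_um, provenance=provenance)


def write_image(image: ImageGrid, path: str | os.PathLike) -> None:
    """Write an :class:`ImageGrid` bit-exactly (TIFF or PNG by extension)."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Serialize a mask as an 8-bit image: foreground 255, background 0."""
    path = Path(path)
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_table(
    records: "pd.DataFrame | Iterable[Mapping] | object",
    path: str | os.PathLike,
) -> None:
    """Write tabular results (aggregate tables, metric rows) as a CSV.

    Accepts a pandas DataFrame, any iterable of mappings, or an object with a
    ``to_dataframe()`` method (e.g. :class:`~plateletquant.quantify.AggregateTable`).
    The column order of the first record is preserved; a header row is always
    written, even for an empty table.
    """
    if records is None:
        raise ValueError("records must not be None")
    if hasattr(records, "to_dataframe"):
        df = records.to_dataframe()
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
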