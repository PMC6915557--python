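"""Channel alignment and region-of-interest construction.

A microfluidic channel imaged on a microscope stage is usually slightly
rotated with respect to the camera raster.  The misalignment angle α is
defined so that a positive α means the channel's top wall descends from left
to right (image rows increase downward).  After rotation correction, two
rectangular regions of interest are cut from the channel band:

* **ROI #1** — the full band between the channel walls, used to estimate the
  intensity threshold.  It deliberately includes the near-wall rim where
  aggregates accumulate, so the histogram always contains foreground signal.
* **ROI #2** — ROI #1 inset by a rim (default 50 µm) from both walls and from
  the left/right image borders, used for coverage quantification.  The inset
  excludes the low-shear edge region where deposition is not representative
  of the bulk wall shear rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.transform import rotate as _sk_rotate

from .io import ImageGrid

__all__ = [
    "ChannelGeometry",
    "RegionOfInterest",
    "WallDetectionError",
    "angle_from_wall_points",
    "detect_wall_automatic",
    "rotate_correct",
    "build_rois",
]


class WallDetectionError(ValueError):
    """Raised when no channel wall can be located in the image."""


@dataclass
class ChannelGeometry:
    """Misalignment angle and top-wall location of a channel.

    ``top_wall_row_left``/``top_wall_row_right`` are the (sub-pixel) rows at
    which the top wall crosses the left and right image borders.  After
    rotation about the image centre the wall sits at approximately their
    mean, which is what :func:`build_rois` uses.
    """

    alpha_deg: float
    top_wall_row_left: float
    top_wall_row_right: float
    channel_width_um: float = 300.0
    rim_um: float = 50.0

    def __post_init__(self) -> None:
        if abs(self.alpha_deg) >= 45:
            raise ValueError(f"|alpha_deg| must be < 45, got {self.alpha_deg}")
        if self.channel_width_um <= 0 or self.rim_um < 0:
            raise ValueError("channel_width_um must be > 0 and rim_um >= 0")

    @property
    def top_wall_row(self) -> float:
        """Wall row after rotation correction about the image centre."""
        return 0.5 * (self.top_wall_row_left + self.top_wall_row_right)


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel bounds [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    label: str = "ROI1"

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError("invalid row bounds")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError("invalid column bounds")
        if self.label not in ("ROI1", "ROI2"):
            raise ValueError("label must be 'ROI1' or 'ROI2'")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)

    @property
    def n_pixels(self) -> int:
        r, c = self.shape
        return r * c

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_end), slice(self.col_start, self.col_end))

    def extract(self, image: ImageGrid) -> np.ndarray:
        """Return a copy of the image pixels inside the ROI."""
        nrow, ncol = image.shape
        if self.row_end > nrow or self.col_end > ncol:
            raise ValueError(f"{self.label} exceeds the image extent {image.shape}")
        return image.pixels[self.slices].copy()

    def contains(self, other: "RegionOfInterest") -> bool:
        return (
            self.row_start <= other.row_start
            and other.row_end <= self.row_end
            and self.col_start <= other.col_start
            and other.col_end <= self.col_end
        )


def angle_from_wall_points(
    left_point: tuple[float, float],
    right_point: tuple[float, float],
    channel_width_um: float = 300.0,
    rim_um: float = 50.0,
) -> ChannelGeometry:
    """Misalignment angle from two manually indicated wall/border crossings.

    ``left_point`` and ``right_point`` are (row, col) coordinates of the top
    wall at the left and right image borders.  The angle is the arctangent of
    Δrow/Δcol; positive when the wall descends from left to right.
    """
    (r_l, c_l), (r_r, c_r) = left_point, right_point
    if c_l == c_r:
        raise ValueError("wall points must lie on distinct columns")
    if c_l > c_r:
        (r_l, c_l), (r_r, c_r) = (r_r, c_r), (r_l, c_l)
    alpha = math.degrees(math.atan2(r_r - r_l, c_r - c_l))
    if abs(alpha) >= 45:
        raise ValueError(f"implausible wall angle {alpha:.1f} deg (|alpha| >= 45)")
    return ChannelGeometry(
        alpha_deg=alpha,
        top_wall_row_left=float(r_l),
        top_wall_row_right=float(r_r),
        channel_width_um=channel_width_um,
        rim_um=rim_um,
    )


def _rotate_float(pixels: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the raster centre; exposed corners filled with 0."""
    return _sk_rotate(
        pixels.astype(float), angle_deg, resize=False, order=1, cval=0.0,
        preserve_range=True,
    )


def _first_local_max_rows(
    pixels: np.ndarray, threshold: float, smooth: int = 5
) -> np.ndarray:
    """Per-column row of the first local intensity maximum above ``threshold``.

    Each column is smoothed with a ``smooth``-pixel moving average, then
    scanned top to bottom for the first row r with
    I(r-1) < I(r) >= I(r+1) and I(r) > threshold.  Columns with no such row
    are returned as NaN.
    """
    s = uniform_filter1d(pixels.astype(float), size=smooth, axis=0, mode="nearest")
    mid = s[1:-1]
    is_max = (s[:-2] < mid) & (mid >= s[2:]) & (mid > threshold)
    any_max = is_max.any(axis=0)
    first = np.argmax(is_max, axis=0) + 1.0
    first[~any_max] = np.nan
    return first


def _background_stats(pixels: np.ndarray, n_rows: int = 10) -> tuple[float, float]:
    """Mean and SD of the raw pixels in the top ``n_rows`` rows (pooled).

    Exact zeros are excluded: an already-rotated input carries zero-filled
    corner wedges that would otherwise drag the estimate down.
    """
    top = pixels[:n_rows].astype(float)
    vals = top[top > 0]
    if vals.size < 50:
        vals = top.ravel()
    return float(vals.mean()), float(vals.std())


def detect_wall_automatic(
    image: ImageGrid,
    sweep_range_deg: float = 5.0,
    sweep_step_deg: float = 0.05,
    channel_width_um: float = 300.0,
    rim_um: float = 50.0,
) -> ChannelGeometry:
    """Locate the top channel wall and the misalignment angle automatically.

    Each column is scanned top to bottom for its first local intensity
    maximum — the top wall.  An angle sweep then tries every candidate angle
    on a uniform grid over ±``sweep_range_deg``; for each candidate the image
    is rotated and the variance of the per-column wall rows is taken as the
    (negated) alignment score.  The wall is flat exactly when the rotation
    cancels the stage misalignment, so the best candidate is the variance
    minimizer.  Deterministic for fixed inputs.
    """
    if sweep_range_deg <= 0 or sweep_range_deg > 10:
        raise ValueError("sweep_range_deg must be in (0, 10]")
    if sweep_step_deg <= 0:
        raise ValueError("sweep_step_deg must be positive")
    pixels = image.pixels
    if pixels.min() == pixels.max():
        raise WallDetectionError("no wall detected: constant-intensity image")
    bg_mean, bg_sd = _background_stats(pixels)
    threshold = bg_mean + 2.0 * bg_sd

    n_steps = int(round(sweep_range_deg / sweep_step_deg))
    candidates = np.arange(-n_steps, n_steps + 1) * sweep_step_deg
    n_rows_img, n_cols = pixels.shape
    # Rotation exposes zero-filled wedges along the borders; columns within
    # the worst-case wedge width never carry reliable wall pixels and are
    # excluded from the alignment score for every candidate alike.
    margin = math.ceil(math.tan(math.radians(sweep_range_deg)) * n_rows_img)
    cols = slice(margin, n_cols - margin) if n_cols > 2 * margin + 10 else slice(None)

    best_angle = None
    best_var = np.inf
    best_rows = None
    for angle in candidates:
        rot = _rotate_float(pixels, angle) if angle != 0.0 else pixels.astype(float)
        rows = _first_local_max_rows(rot[:, cols], threshold)
        valid = ~np.isnan(rows)
        if valid.sum() <= rows.size / 2:
            continue
        var = float(np.var(rows[valid]))
        if var < best_var:
            best_var, best_angle, best_rows = var, float(angle), rows
    if best_angle is None:
        raise WallDetectionError(
            "no wall detected: fewer than half of the columns show a local "
            "intensity maximum at every candidate angle"
        )
    top_row = float(np.nanmean(best_rows))
    return ChannelGeometry(
        alpha_deg=best_angle,
        top_wall_row_left=top_row,
        top_wall_row_right=top_row,
        channel_width_um=channel_width_um,
        rim_um=rim_um,
    )


def rotate_correct(image: ImageGrid, geometry: ChannelGeometry) -> ImageGrid:
    """Rotate the image so the channel walls become horizontal.

    The correction rotates by the geometry's angle α about the image centre
    with bilinear interpolation; exposed corners are filled with 0 and the
    result is clipped back to the valid intensity range.  α = 0 returns a
    bit-exact copy.
    """
    if geometry.alpha_deg == 0.0:
        return image.copy()
    rot = _rotate_float(image.pixels, geometry.alpha_deg)
    rot = np.clip(np.rint(rot), 0, image.max_value)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    return ImageGrid(
        rot.astype(dtype),
        image.bit_depth,
        image.pixel_size_um,
        name=image.name + "_rot" if image.name else "",
    )


def build_rois(
    image: ImageGrid, geometry: ChannelGeometry
) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Construct ROI #1 (full channel band) and ROI #2 (rim-inset region).

    The image must already be angle-corrected.  ROI #1 spans the rows from
    the top wall down by the channel width, over all columns.  ROI #2 shrinks
    ROI #1 by ``ceil(rim_um / pixel_size_um)`` pixels at the walls (top and
    bottom) and at the left/right image borders.
    """
    top = int(round(geometry.top_wall_row))
    width_px = int(round(geometry.channel_width_um / image.pixel_size_um))
    nrow, ncol = image.shape
    if top < 0 or top + width_px > nrow:
        raise ValueError(
            f"channel band rows [{top}, {top + width_px}) do not fit in the "
            f"raster of {nrow} rows"
        )
    roi1 = RegionOfInterest(top, top + width_px, 0, ncol, label="ROI1")
    rim_px = math.ceil(geometry.rim_um / image.pixel_size_um)
    r0, r1 = top + rim_px, top + width_px - rim_px
    c0, c1 = rim_px, ncol - rim_px
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            "empty ROI2: the rim inset leaves no pixels "
            f"(channel width {geometry.channel_width_um} um, rim {geometry.rim_um} um)"
        )
    roi2 = RegionOfInterest(r0, r1, c0, c1, label="ROI2")
    return roi1, roi2
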