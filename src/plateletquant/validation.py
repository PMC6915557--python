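"""Pixel-wise validation of triangle masks against manual annotations.

A triangle-derived mask is compared pixel by pixel with a reference mask
(manually drawn, or the known ground truth of a synthetic image).  The
confusion counts give sensitivity, specificity and accuracy; coverage pairs
from many images are summarized by the coefficient of determination of the
scatter against the identity line y = x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import BinaryMask

__all__ = [
    "ConfusionMetrics",
    "CoveragePair",
    "confusion",
    "pooled_confusion",
    "r_squared_vs_identity",
    "polygons_to_mask",
]

REFERENCE_PROVENANCES = ("manual", "synthetic_truth")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Pixel-wise confusion counts with the reference mask as ground truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pixels(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity_pct(self) -> float:
        """100 * TP / (TP + FN); NaN if the reference has no foreground."""
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity_pct(self) -> float:
        """100 * TN / (TN + FP); NaN if the reference has no background."""
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n_pixels

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class CoveragePair:
    """Coverage of one image measured manually and by the triangle method."""

    manual_pct: float
    triangle_pct: float
    image_id: str = ""
    condition: str = "untreated"

    def __post_init__(self) -> None:
        if self.manual_pct < 0 or self.triangle_pct < 0:
            raise ValueError("coverages must be non-negative")
        if self.condition not in ("untreated", "activated"):
            raise ValueError("condition must be 'untreated' or 'activated'")


def confusion(test: BinaryMask, reference: BinaryMask) -> ConfusionMetrics:
    """Pixel-wise confusion matrix of ``test`` against ``reference``.

    The reference mask is the ground truth (its provenance must be ``manual``
    or ``synthetic_truth``); a true positive is a pixel foreground in both.
    """
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {reference.shape}")
    if reference.provenance not in REFERENCE_PROVENANCES:
        raise ValueError(
            f"reference provenance must be one of {REFERENCE_PROVENANCES}, "
            f"got {reference.provenance!r}"
        )
    t, r = test.pixels, reference.pixels
    tp = int(np.count_nonzero(t & r))
    fp = int(np.count_nonzero(t & ~r))
    fn = int(np.count_nonzero(~t & r))
    tn = t.size - tp - fp - fn
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def pooled_confusion(
    pairs: Sequence[tuple[BinaryMask, BinaryMask]]
) -> ConfusionMetrics:
    """Micro-averaged confusion over many (test, reference) mask pairs.

    Counts are summed across pairs before the percentages are formed, so
    large images weigh proportionally more — matching the superposition of
    all masks into one comparison.
    """
    if not pairs:
        raise ValueError("at least one mask pair is required")
    total = ConfusionMetrics(0, 0, 0, 0)
    for test, reference in pairs:
        total = total + confusion(test, reference)
    return total


def r_squared_vs_identity(pairs: Iterable[CoveragePair]) -> float:
    """R² of triangle vs manual coverage measured against the line y = x.

    Residuals are taken against the identity line (triangle_i − manual_i) and
    the total variance against the mean of the triangle-axis values:

        R² = 1 − Σ (t_i − m_i)² / Σ (t_i − mean(t))²

    Unlike an ordinary regression R², this can be negative when agreement
    with the identity line is worse than predicting the mean.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("at least two coverage pairs are required")
    t = np.array([p.triangle_pct for p in pairs], dtype=float)
    m = np.array([p.manual_pct for p in pairs], dtype=float)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in triangle coverages; R^2 undefined")
    ss_res = float(np.sum((t - m) ** 2))
    return 1.0 - ss_res / ss_tot


def polygons_to_mask(
    polygons: Iterable[Sequence[tuple[float, float]]],
    shape: tuple[int, int],
    pixel_size_um: float,
    provenance: str = "manual",
) -> BinaryMask:
    """Rasterize freeform closed outlines into a binary mask.

    Each polygon is a closed loop of (row, col) vertices, as produced by
    drawing freeform lines around aggregates.  Loops are combined by even-odd
    (XOR) rasterization, so a loop drawn inside another punches a hole.
    """
    from skimage.draw import polygon as _sk_polygon

    mask = np.zeros(shape, dtype=bool)
    for loop in polygons:
        verts = np.asarray(loop, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("each polygon needs at least three (row, col) vertices")
        rr, cc = _sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
        fill = np.zeros(shape, dtype=bool)
        fill[rr, cc] = True
        mask ^= fill
    return BinaryMask(mask, pixel_size_um, provenance=provenance)
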