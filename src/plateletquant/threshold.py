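"""Triangle thresholding of unimodal fluorescence histograms.

Fluorescence images of adhered platelets have a strongly skewed unimodal
histogram: a tall background peak with a long, low tail of bright aggregate
pixels.  The triangle method places the threshold at the "base" of that
peak.  The construction:

1. Build the intensity histogram of ROI #1.
2. Find the **artificial zero**: scanning from the peak toward higher
   intensities, the first bin whose count falls below 0.01% of the maximum
   count (falling back to the last bin if none does).
3. Crop the histogram to [peak, artificial zero], normalize both axes to the
   unit square, and draw the hypotenuse from (0, 1) — the peak — to
   (1, c_z/c_max) — the artificial zero.
4. For every bin, measure the orthogonal (point-to-segment) distance between
   the histogram point and the hypotenuse; the bin with the maximum distance
   is the threshold (ties broken toward the lower bin, peak excluded).

The threshold found on ROI #1 is then applied to ROI #2.  Estimating on
ROI #1 matters: with no foreground anywhere the triangle construction would
split the background peak itself and report a grossly exaggerated coverage,
but aggregates accumulating in the near-wall rim (inside ROI #1, outside
ROI #2) keep the histogram tail populated.  As a safety net, a histogram
whose tail is not meaningfully longer than the background peak width trips
an :class:`EmptySignalError` instead of returning a background-splitting
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RegionOfInterest
from .io import BinaryMask, ImageGrid

__all__ = [
    "IntensityHistogram",
    "TriangleResult",
    "EmptySignalError",
    "histogram",
    "find_artificial_zero",
    "triangle",
    "apply_threshold",
    "DEFAULT_MIN_TAIL_RATIO",
]

ARTIFICIAL_ZERO_FRACTION = 1e-4  # 0.01% of the maximum count

#: Minimum ratio of the right tail span (peak -> artificial zero) to the left
#: span of the peak at the same 0.01% cutoff.  Any symmetric background
#: distribution gives a ratio near 1 regardless of its width, while genuine
#: foreground signal stretches the right side many-fold, so a value of 3
#: cleanly separates "background only" from "background plus aggregates".
DEFAULT_MIN_TAIL_RATIO = 3.0


class EmptySignalError(ValueError):
    """The histogram shows no foreground tail; a threshold would be meaningless."""


@dataclass
class IntensityHistogram:
    """Binned intensity counts of one region of interest."""

    bin_edges: np.ndarray
    counts: np.ndarray
    source_roi: str = "ROI1"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have length len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class TriangleResult:
    """Outcome of the triangle construction on a cropped histogram."""

    peak_bin: int
    zero_bin: int
    threshold_bin: int
    threshold_value: float
    distances: np.ndarray

    def __post_init__(self) -> None:
        if not (self.peak_bin < self.threshold_bin <= self.zero_bin):
            raise ValueError("expected peak_bin < threshold_bin <= zero_bin")


def histogram(
    image: ImageGrid, roi: RegionOfInterest, n_bins: int | None = None
) -> IntensityHistogram:
    """Uniform-bin intensity histogram of an ROI, spanning [0, 2^bit_depth).

    The default bin count is the native intensity resolution for 8-bit data
    (256) and 1024 for 16-bit data.
    """
    if n_bins is None:
        n_bins = 256 if image.bit_depth == 8 else 1024
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    values = roi.extract(image)
    if values.size == 0:
        raise ValueError("empty ROI")
    edges = np.linspace(0, 2**image.bit_depth, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return IntensityHistogram(edges, counts, source_roi=roi.label)


def find_artificial_zero(hist: IntensityHistogram) -> int:
    """First bin beyond the peak whose count drops below 0.01% of the maximum.

    Scanning starts just above the peak bin and moves toward higher
    intensities; if no bin falls below the cutoff the last bin is returned.
    """
    counts = np.asarray(hist.counts)
    if counts.max() == 0:
        raise ValueError("all-zero histogram")
    peak = int(np.argmax(counts))
    cutoff = ARTIFICIAL_ZERO_FRACTION * counts[peak]
    below = np.nonzero(counts[peak + 1 :] < cutoff)[0]
    if below.size:
        return peak + 1 + int(below[0])
    return hist.n_bins - 1


def _left_span_bins(counts: np.ndarray, peak: int) -> int:
    """Bins from the peak down to the 0.01%-of-max cutoff on the *left* side.

    Mirrors the artificial-zero scan toward lower intensities; used as a
    signal-free yardstick for the width of the background peak.
    """
    cutoff = ARTIFICIAL_ZERO_FRACTION * counts[peak]
    below = np.nonzero(counts[:peak][::-1] < cutoff)[0]
    if below.size:
        return int(below[0]) + 1
    return max(peak, 1)


def _point_segment_distances(x: np.ndarray, y: np.ndarray,
                             p0: tuple[float, float], p1: tuple[float, float]) -> np.ndarray:
    """Euclidean distance from each point (x_i, y_i) to the segment p0-p1."""
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    denom = dx * dx + dy * dy
    t = ((x - p0[0]) * dx + (y - p0[1]) * dy) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(x - (p0[0] + t * dx), y - (p0[1] + t * dy))


def triangle(
    hist: IntensityHistogram,
    min_tail_ratio: float = DEFAULT_MIN_TAIL_RATIO,
) -> TriangleResult:
    """Triangle threshold of a skewed unimodal histogram.

    Set ``min_tail_ratio=0`` to disable the empty-signal guard (e.g. when
    analysing the bare geometric construction).

    Raises
    ------
    EmptySignalError
        If the histogram has no tail beyond the peak, or the tail is shorter
        than ``min_tail_ratio`` times the peak's full width at half maximum —
        the signature of an image with no foreground signal.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.max() == 0:
        raise ValueError("all-zero histogram")
    peak = int(np.argmax(counts))
    zero = find_artificial_zero(hist)
    if zero <= peak:
        raise EmptySignalError(
            "no intensity tail beyond the histogram peak; the image appears "
            "to contain no foreground signal"
        )
    if min_tail_ratio > 0:
        left = _left_span_bins(counts, peak)
        ratio = (zero - peak) / left
        if ratio < min_tail_ratio:
            raise EmptySignalError(
                f"histogram tail ({zero - peak} bins) is only {ratio:.2f}x the "
                f"left half-width of the peak ({left} bins); a triangle "
                f"threshold would split the background "
                f"(required ratio {min_tail_ratio})"
            )

    sub = counts[peak : zero + 1]
    n = len(sub)
    x = np.arange(n, dtype=float) / (n - 1)
    y = sub / counts[peak]
    dist = _point_segment_distances(x, y, (0.0, 1.0), (1.0, float(y[-1])))
    # The peak itself is excluded from the argmax; ties break toward the
    # lower bin (first occurrence), keeping the threshold conservative.
    # Distances are quantized so exact geometric ties (e.g. a collinear
    # ramp) are not broken by floating-point dust.
    offset = 1 + int(np.argmax(np.round(dist[1:], 12)))
    threshold_bin = peak + offset
    return TriangleResult(
        peak_bin=peak,
        zero_bin=zero,
        threshold_bin=threshold_bin,
        threshold_value=float(hist.bin_edges[threshold_bin]),
        distances=dist,
    )


def apply_threshold(
    image: ImageGrid, roi2: RegionOfInterest, result: TriangleResult
) -> BinaryMask:
    """Binarize ROI #2 with the triangle threshold (foreground strictly above).

    Pixels exactly at the threshold value are background: the threshold bin
    sits at the base of the background peak and its own pixels are
    background-like.
    """
    values = roi2.extract(image)
    return BinaryMask(
        values > result.threshold_value,
        image.pixel_size_um,
        provenance="triangle",
    )
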