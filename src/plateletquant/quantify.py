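"""Platelet coverage and aggregate size distribution from a binary mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .io import BinaryMask

__all__ = [
    "AggregateRecord",
    "AggregateTable",
    "CoverageResult",
    "SizeDistribution",
    "coverage",
    "label_aggregates",
    "size_distribution",
    "default_size_bins_um2",
]

COVERAGE_FORMULAS = ("fraction_of_total", "white_over_black")


@dataclass(frozen=True)
class AggregateRecord:
    """One connected component of the thresholded mask."""

    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (row_start, row_end, col_start, col_end)
    equivalent_diameter_um: float


@dataclass
class AggregateTable:
    """Per-aggregate records plus the pixel-size calibration they were measured at."""

    records: list[AggregateRecord]
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([r.area_um2 for r in self.records], dtype=float)

    @property
    def total_area_px(self) -> int:
        return int(sum(r.area_px for r in self.records))

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "label", "area_px", "area_um2", "centroid_row", "centroid_col",
            "bbox_row_start", "bbox_row_end", "bbox_col_start", "bbox_col_end",
            "equivalent_diameter_um",
        ]
        rows = [
            (
                r.label, r.area_px, r.area_um2, r.centroid[0], r.centroid[1],
                r.bbox[0], r.bbox[1], r.bbox[2], r.bbox[3],
                r.equivalent_diameter_um,
            )
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class CoverageResult:
    """Platelet coverage of one mask, as a percentage."""

    coverage_pct: float
    n_foreground_px: int
    n_background_px: int
    roi_label: str = "ROI2"
    formula: str = "fraction_of_total"


def coverage(
    mask: BinaryMask,
    formula: str = "fraction_of_total",
    roi_label: str = "ROI2",
) -> CoverageResult:
    """Platelet coverage of a mask.

    Two conventions are supported and made explicit because they diverge at
    high coverage:

    * ``fraction_of_total`` (default): 100 x white / (white + black) — the
      fraction of the ROI area covered.
    * ``white_over_black``: 100 x white / black — the white-to-black pixel
      ratio.  Undefined (error) when there are no background pixels.

    At coverages of a few percent the two differ by well under a tenth of a
    percentage point.
    """
    if formula not in COVERAGE_FORMULAS:
        raise ValueError(f"formula must be one of {COVERAGE_FORMULAS}")
    n_white = int(mask.pixels.sum())
    n_black = int(mask.pixels.size - n_white)
    if n_white == 0:
        pct = 0.0
    elif formula == "fraction_of_total":
        pct = 100.0 * n_white / (n_white + n_black)
    else:
        if n_black == 0:
            raise ValueError("white_over_black is undefined for an all-white mask")
        pct = 100.0 * n_white / n_black
    return CoverageResult(pct, n_white, n_black, roi_label=roi_label, formula=formula)


def label_aggregates(mask: BinaryMask, connectivity: int = 8) -> AggregateTable:
    """Connected-component analysis of the platelet mask.

    Components are labelled in raster-scan order of their first pixel.  The
    default 8-connectivity matches the convention of MATLAB-style
    ``regionprops`` analyses; 4-connectivity separates diagonally touching
    blobs.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    sk_conn = 1 if connectivity == 4 else 2
    labels = measure.label(mask.pixels, connectivity=sk_conn)
    px = mask.pixel_size_um
    records = []
    for rp in measure.regionprops(labels):
        r0, c0, r1, c1 = rp.bbox
        records.append(
            AggregateRecord(
                label=int(rp.label),
                area_px=int(rp.area),
                area_um2=float(rp.area) * px * px,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=(int(r0), int(r1), int(c0), int(c1)),
                equivalent_diameter_um=float(rp.equivalent_diameter_area) * px,
            )
        )
    return AggregateTable(records, pixel_size_um=px)


def default_size_bins_um2(
    lo: float = 1.0, hi: float = 1e4, per_decade: int = 10
) -> np.ndarray:
    """Logarithmic aggregate-size bins: ``per_decade`` bins per decade."""
    n_decades = np.log10(hi / lo)
    return np.logspace(np.log10(lo), np.log10(hi), int(round(n_decades * per_decade)) + 1)


@dataclass
class SizeDistribution:
    """Histogram of aggregate areas; out-of-range aggregates counted separately."""

    bin_edges_um2: np.ndarray
    counts: np.ndarray
    n_out_of_range: int

    @property
    def n_in_range(self) -> int:
        return int(self.counts.sum())


def size_distribution(
    table: AggregateTable, bin_edges_um2: np.ndarray | list[float] | None = None
) -> SizeDistribution:
    """Aggregate size distribution over the given (strictly increasing) bin edges.

    Aggregates with areas outside [first edge, last edge) land in the
    ``n_out_of_range`` bucket rather than being silently dropped.
    """
    if bin_edges_um2 is None:
        bin_edges_um2 = default_size_bins_um2()
    edges = np.asarray(bin_edges_um2, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    areas = table.areas_um2
    in_range = (areas >= edges[0]) & (areas < edges[-1])
    counts, _ = np.histogram(areas[in_range], bins=edges)
    return SizeDistribution(edges, counts, n_out_of_range=int((~in_range).sum()))
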