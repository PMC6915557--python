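"""End-to-end analysis: align, crop, threshold, quantify."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    ChannelGeometry,
    RegionOfInterest,
    angle_from_wall_points,
    build_rois,
    detect_wall_automatic,
    rotate_correct,
)
from .io import BinaryMask, ImageGrid
from .quantify import (
    AggregateTable,
    CoverageResult,
    SizeDistribution,
    coverage,
    label_aggregates,
    size_distribution,
)
from .threshold import (
    EmptySignalError,
    IntensityHistogram,
    TriangleResult,
    apply_threshold,
    histogram,
    triangle,
)

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    """Everything the pipeline measured on one image.

    If the ROI #1 histogram showed no foreground tail (``degenerate=True``)
    no threshold exists; the mask is empty and the coverage is zero, which is
    the correct call for an image without any detectable aggregates.
    """

    geometry: ChannelGeometry
    corrected: ImageGrid
    roi1: RegionOfInterest
    roi2: RegionOfInterest
    histogram: IntensityHistogram
    triangle: TriangleResult | None
    mask: BinaryMask
    coverage: CoverageResult
    aggregates: AggregateTable
    sizes: SizeDistribution
    degenerate: bool = False


def analyze(
    image: ImageGrid,
    geometry: ChannelGeometry | None = None,
    wall_points: tuple[tuple[float, float], tuple[float, float]] | None = None,
    channel_width_um: float = 300.0,
    rim_um: float = 50.0,
    n_bins: int | None = None,
    coverage_formula: str = "fraction_of_total",
    min_area_um2: float = 0.0,
    connectivity: int = 8,
    sweep_range_deg: float = 5.0,
    sweep_step_deg: float = 0.05,
) -> AnalysisResult:
    """Run the full pipeline on one fluorescence image.

    The channel geometry is taken (in order of precedence) from an explicit
    ``geometry``, from manual ``wall_points`` (left and right border
    crossings of the top wall), or from automatic wall detection.  The
    threshold is estimated on ROI #1 and applied to ROI #2; coverage and the
    aggregate size distribution are measured on the resulting mask.
    ``min_area_um2 > 0`` drops connected components smaller than that area
    from both the table and the coverage (off by default).
    """
    if geometry is None:
        if wall_points is not None:
            geometry = angle_from_wall_points(
                wall_points[0], wall_points[1],
                channel_width_um=channel_width_um, rim_um=rim_um,
            )
        else:
            geometry = detect_wall_automatic(
                image,
                sweep_range_deg=sweep_range_deg,
                sweep_step_deg=sweep_step_deg,
                channel_width_um=channel_width_um,
                rim_um=rim_um,
            )
    corrected = rotate_correct(image, geometry)
    roi1, roi2 = build_rois(corrected, geometry)
    hist = histogram(corrected, roi1, n_bins=n_bins)
    degenerate = False
    try:
        tri: TriangleResult | None = triangle(hist)
    except EmptySignalError:
        tri = None
        degenerate = True
    if tri is not None:
        mask = apply_threshold(corrected, roi2, tri)
    else:
        mask = BinaryMask(
            np.zeros(roi2.shape, dtype=bool), image.pixel_size_um, provenance="triangle"
        )
    table = label_aggregates(mask, connectivity=connectivity)
    if min_area_um2 > 0 and len(table):
        keep = [r for r in table if r.area_um2 >= min_area_um2]
        pruned = np.zeros(mask.shape, dtype=bool)
        if keep:
            from skimage import measure as _measure

            sk_conn = 1 if connectivity == 4 else 2
            labels = _measure.label(mask.pixels, connectivity=sk_conn)
            keep_labels = {r.label for r in keep}
            pruned = np.isin(labels, list(keep_labels))
        mask = BinaryMask(pruned, image.pixel_size_um, provenance="triangle")
        table = label_aggregates(mask, connectivity=connectivity)
    cov = coverage(mask, formula=coverage_formula)
    sizes = size_distribution(table)
    return AnalysisResult(
        geometry=geometry,
        corrected=corrected,
        roi1=roi1,
        roi2=roi2,
        histogram=hist,
        triangle=tri,
        mask=mask,
        coverage=cov,
        aggregates=table,
        sizes=sizes,
        degenerate=degenerate,
    )
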