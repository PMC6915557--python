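"""Triangle construction: artificial zero, distance geometry, guard, transfer."""

from __future__ import annotations

import math

import numpy as np
import pytest

from plateletquant.geometry import build_rois
from plateletquant.io import ImageGrid
from plateletquant.pipeline import analyze
from plateletquant.threshold import (
    EmptySignalError,
    IntensityHistogram,
    apply_threshold,
    find_artificial_zero,
    histogram,
    triangle,
)


def hist_from_counts(counts):
    counts = np.asarray(counts)
    return IntensityHistogram(np.arange(len(counts) + 1, dtype=float), counts)


def brute_force_triangle_bin(counts):
    """Independent oracle: scalar point-to-segment maximizer on the cropped,
    unit-square-normalized histogram.  Scans every candidate bin explicitly.
    """
    counts = [float(c) for c in counts]
    peak = counts.index(max(counts))
    cutoff = 1e-4 * counts[peak]
    zero = None
    for i in range(peak + 1, len(counts)):
        if counts[i] < cutoff:
            zero = i
            break
    if zero is None:
        zero = len(counts) - 1
    assert zero > peak, "oracle needs a right-side tail"
    n = zero - peak + 1
    x0, y0 = 0.0, 1.0
    x1, y1 = 1.0, counts[zero] / counts[peak]
    best_i, best_d = None, -1.0
    for i in range(1, n):  # peak itself excluded, ties keep the lower bin
        x = i / (n - 1)
        y = counts[peak + i] / counts[peak]
        # point-to-segment distance, scalar arithmetic
        vx, vy = x1 - x0, y1 - y0
        t = ((x - x0) * vx + (y - y0) * vy) / (vx * vx + vy * vy)
        t = min(max(t, 0.0), 1.0)
        d = math.hypot(x - (x0 + t * vx), y - (y0 + t * vy))
        if d > best_d + 1e-12:
            best_d, best_i = d, i
    return peak + best_i


def random_tail_histogram(rng, n_bins=256):
    """A geometric-decay background peak plus optional bright bumps."""
    counts = np.zeros(n_bins)
    peak_pos = rng.integers(5, 40)
    decay = rng.uniform(0.55, 0.9)
    height = rng.integers(10_000, 200_000)
    idx = np.arange(n_bins)
    counts = height * decay ** np.abs(idx - peak_pos).astype(float)
    counts = np.floor(counts)
    for _ in range(rng.integers(0, 4)):
        center = rng.integers(peak_pos + 30, n_bins - 10)
        width = rng.uniform(2, 12)
        amp = rng.integers(5, 2000)
        counts += np.floor(amp * np.exp(-0.5 * ((idx - center) / width) ** 2))
    return counts.astype(int)


class TestHistogram:
    def test_uniform_roi_fills_one_bin(self):
        img = ImageGrid(np.zeros((20, 20), dtype=np.uint8), 8, 1.0)
        from plateletquant.geometry import RegionOfInterest

        roi = RegionOfInterest(0, 10, 0, 10)
        h = histogram(img, roi, n_bins=256)
        assert h.counts[0] == 100 and h.counts[1:].sum() == 0

    def test_counts_conserve_roi_pixel_count(self, rng):
        img = ImageGrid(rng.integers(0, 256, (50, 60), dtype=np.uint8), 8, 1.0)
        from plateletquant.geometry import RegionOfInterest

        roi = RegionOfInterest(3, 47, 5, 55)
        for n_bins in (16, 64, 256):
            h = histogram(img, roi, n_bins=n_bins)
            assert h.counts.sum() == roi.n_pixels

    def test_two_level_roi(self):
        arr = np.full((10, 10), 10, dtype=np.uint8)
        arr[5:] = 200
        img = ImageGrid(arr, 8, 1.0)
        from plateletquant.geometry import RegionOfInterest

        h = histogram(img, RegionOfInterest(0, 10, 0, 10), n_bins=256)
        nz = np.nonzero(h.counts)[0]
        assert list(nz) == [10, 200]
        assert h.counts[10] == h.counts[200] == 50

    def test_too_few_bins_rejected(self):
        img = ImageGrid(np.zeros((4, 4), dtype=np.uint8), 8, 1.0)
        from plateletquant.geometry import RegionOfInterest

        with pytest.raises(ValueError):
            histogram(img, RegionOfInterest(0, 4, 0, 4), n_bins=8)


class TestArtificialZero:
    def test_stated_rule(self):
        # first bin with count < 0.01% of 10000 (i.e. < 1)
        assert find_artificial_zero(hist_from_counts([10000, 500, 20, 0, 0, 3])) == 3

    def test_fallback_to_last_bin(self):
        assert find_artificial_zero(hist_from_counts([100, 90, 80, 70])) == 3

    def test_all_zero_histogram_raises(self):
        with pytest.raises(ValueError):
            find_artificial_zero(hist_from_counts([0, 0, 0]))


class TestTriangle:
    def test_matches_oracle_on_spec_shape(self):
        counts = [100, 50, 25, 12, 6, 3, 1, 0]
        res = triangle(hist_from_counts(counts), min_tail_ratio=0)
        assert res.threshold_bin == brute_force_triangle_bin(counts)

    def test_collinear_ramp_breaks_tie_just_after_peak(self):
        res = triangle(hist_from_counts([100, 80, 60, 40, 20, 0]), min_tail_ratio=0)
        assert np.allclose(res.distances, 0, atol=1e-12)
        assert res.threshold_bin == 1

    def test_two_bin_minimal_case(self):
        res = triangle(hist_from_counts([100, 0]), min_tail_ratio=0)
        assert res.threshold_bin == res.zero_bin == 1

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(202)
        for _ in range(50):
            counts = random_tail_histogram(rng)
            res = triangle(hist_from_counts(counts), min_tail_ratio=0)
            assert res.threshold_bin == brute_force_triangle_bin(counts)

    def test_distance_maximizer_invariant(self):
        rng = np.random.default_rng(7)
        counts = random_tail_histogram(rng)
        res = triangle(hist_from_counts(counts), min_tail_ratio=0)
        assert res.peak_bin < res.threshold_bin <= res.zero_bin
        assert np.all(res.distances >= 0)
        i = res.threshold_bin - res.peak_bin
        assert res.distances[i] == pytest.approx(res.distances.max())

    def test_threshold_shifts_with_intensity_offset(self):
        """Adding a constant to every pixel moves the threshold by the same
        amount (to within one bin width)."""
        from plateletquant.synthetic import FixtureSpec, generate

        fx = generate(FixtureSpec(seed=17, wall_intensity=200.0,
                                  aggregate_intensity_mean=160.0))
        shift = 15
        img = fx.image
        assert img.pixels.max() + shift <= img.max_value  # no clipping
        shifted = ImageGrid(
            img.pixels + np.uint8(shift), img.bit_depth, img.pixel_size_um
        )
        roi1, _ = build_rois(img, fx.geometry)
        base = triangle(histogram(img, roi1))
        res = triangle(histogram(shifted, roi1))
        bw = histogram(img, roi1).bin_width
        assert res.threshold_value == pytest.approx(base.threshold_value + shift, abs=bw)

    def test_background_only_image_trips_guard(self, empty_fixture):
        """Without foreground the triangle would split the background peak;
        the guard must refuse instead of returning such a threshold."""
        res = analyze(empty_fixture.image)
        assert res.degenerate
        assert res.triangle is None
        assert res.coverage.coverage_pct == 0.0

    def test_degenerate_no_tail_raises(self):
        # peak in the last bin: no right-side tail at all
        with pytest.raises(EmptySignalError):
            triangle(hist_from_counts([1, 2, 1000]), min_tail_ratio=0)


class TestApplyThreshold:
    def _setup(self, arr):
        img = ImageGrid(arr, 8, 1.0)
        from plateletquant.geometry import RegionOfInterest

        return img, RegionOfInterest(0, arr.shape[0], 0, arr.shape[1], label="ROI2")

    def test_uniform_roi_at_or_below_threshold_is_empty(self, dense_result):
        res = dense_result.triangle
        level = int(res.threshold_value)
        img, roi = self._setup(np.full((6, 6), level, dtype=np.uint8))
        assert apply_threshold(img, roi, res).pixels.sum() == 0
        img2, roi2 = self._setup(np.full((6, 6), level + 1, dtype=np.uint8))
        assert apply_threshold(img2, roi2, res).pixels.sum() == 36

    def test_strict_inequality_and_block_count(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[2:5, 3:6] = 255
        img, roi = self._setup(arr)
        res = triangle(hist_from_counts([91] + [0] * 200 + [9] + [0] * 54),
                       min_tail_ratio=0)
        mask = apply_threshold(img, roi, res)
        assert mask.pixels.sum() == 9
        # pixels exactly at the threshold value stay background
        arr2 = np.full((4, 4), int(res.threshold_value), dtype=np.uint8)
        img2, roi2 = self._setup(arr2)
        assert apply_threshold(img2, roi2, res).pixels.sum() == 0

    def test_threshold_separates_classes_on_default_fixture(
        self, dense_fixture, dense_result
    ):
        """The ROI#1 threshold clears essentially all background yet sits well
        below the aggregate intensity."""
        from scipy.ndimage import binary_dilation

        spec = dense_fixture.spec
        tri = dense_result.triangle
        # background pixels of ROI2 in the corrected frame: truth-negative
        # and clear of the blurred halo around each aggregate
        roi2 = dense_result.roi2
        sub = dense_result.corrected.pixels[roi2.slices]
        halo = binary_dilation(
            dense_fixture.truth_mask_aligned.pixels[roi2.slices], iterations=4
        )
        bg = sub[~halo]
        assert tri.threshold_value > np.percentile(bg, 99.8)
        assert tri.threshold_value < (
            spec.aggregate_intensity_mean - 3 * spec.aggregate_intensity_sd
        )


class TestThresholdTransfer:
    def test_rim_aggregates_support_empty_roi2(self, rim_fixture):
        """Aggregates only in the near-wall rim: the ROI#1 threshold applied to
        ROI#2 yields ~0% coverage, while thresholding ROI#2 alone is refused."""
        res = analyze(rim_fixture.image)
        assert not res.degenerate
        assert res.coverage.coverage_pct < 0.1
        h2 = histogram(res.corrected, res.roi2)
        with pytest.raises(EmptySignalError):
            triangle(h2)
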