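"""Seeded synthetic fluorescence images with known ground truth.

The generator emulates the structure of a fluorescence micrograph of a
perfused microfluidic channel: a dark noisy background, a slightly brighter
channel band bounded by two bright wall lines, sparse bright elliptical
blobs (platelet aggregates) inside the channel, and a small global rotation
mimicking stage misalignment.  Every draw comes from a single seeded
generator, so identical seeds give bit-identical images.

Default intensity scale (8-bit): background 20 ± 3 counts, channel interior
6 counts brighter than the exterior, walls at 230, aggregates at 180 ± 10.
A quiet background of a few counts of read noise on a low offset is typical
for a camera imaging a dark fluorescence field.  Aggregate edges are
softened with a 0.5 px Gaussian blur to mimic slightly out-of-focus
boundaries; the ground-truth mask is captured before the blur, so
segmentation tolerances absorb the resulting halo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _sk_ellipse
from skimage.transform import rotate as _sk_rotate

from .geometry import ChannelGeometry
from .io import BinaryMask, ImageGrid

__all__ = ["FixtureSpec", "Fixture", "generate", "fixture_suite", "rim_only_spec"]

_WALL_HALF_THICKNESS = 1  # wall lines are 3 px thick, centred on the wall row


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic channel image.

    ``rim_only=True`` places every aggregate entirely within 50 µm of a
    channel wall — the scenario in which the threshold must be estimated on
    ROI #1 but applied to an (empty) ROI #2.
    """

    seed: int = 0
    image_shape: tuple[int, int] = (520, 1000)
    bit_depth: int = 8
    pixel_size_um: float = 1.0
    channel_width_um: float = 300.0
    top_wall_row: float = 110.0
    true_alpha_deg: float = 0.0
    wall_intensity: float = 230.0
    background_mean: float = 20.0
    background_sd: float = 2.5
    interior_offset: float = 6.0
    n_aggregates: int = 25
    aggregate_area_um2_range: tuple[float, float] = (300.0, 3000.0)
    aggregate_intensity_mean: float = 180.0
    aggregate_intensity_sd: float = 10.0
    edge_blur_sigma_px: float = 0.5
    rim_um: float = 50.0
    rim_only: bool = False

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.aggregate_intensity_mean <= (
            self.background_mean + 5.0 * self.background_sd
        ):
            raise ValueError(
                "aggregates must be separable: intensity mean must exceed "
                "background_mean + 5*background_sd"
            )
        max_value = 2**self.bit_depth - 1
        for name in ("wall_intensity", "aggregate_intensity_mean", "background_mean"):
            v = getattr(self, name)
            if not (0 <= v <= max_value):
                raise ValueError(f"{name}={v} outside [0, {max_value}]")
        lo, hi = self.aggregate_area_um2_range
        if not (0 < lo <= hi):
            raise ValueError("invalid aggregate_area_um2_range")
        if abs(self.true_alpha_deg) >= 45:
            raise ValueError("|true_alpha_deg| must be < 45")


@dataclass
class Fixture:
    """A generated image with its ground truth.

    ``truth_mask`` lives in the same (rotated) frame as ``image``;
    ``truth_mask_aligned`` is the pre-rotation mask, i.e. the frame an ideal
    rotation correction would restore.
    """

    spec: FixtureSpec
    image: ImageGrid
    truth_mask: BinaryMask
    truth_mask_aligned: BinaryMask
    geometry: ChannelGeometry
    condition: str = "activated"

    @property
    def seed(self) -> int:
        return self.spec.seed


def _sample_blobs(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple]:
    """Sample non-overlapping ellipse parameters (row, col, a, b, theta, value).

    Larger blobs are placed first so dense specs still pack; bounding
    circles (semi-major axis + 1 px) must not intersect.  Raises if a blob
    cannot be placed within 1000 attempts.
    """
    px = spec.pixel_size_um
    lo, hi = spec.aggregate_area_um2_range
    areas = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n_aggregates))
    aspects = rng.uniform(0.6, 1.0, spec.n_aggregates)
    order = np.argsort(-areas)
    top = int(round(spec.top_wall_row))
    width_px = int(round(spec.channel_width_um / px))
    rim_px = int(round(spec.rim_um / px))
    nrow, ncol = spec.image_shape
    inner_top = top + _WALL_HALF_THICKNESS + 2
    inner_bot = top + width_px - _WALL_HALF_THICKNESS - 2

    placed: list[tuple] = []
    for idx in order:
        a = math.sqrt(areas[idx] / (math.pi * aspects[idx])) / px
        b = a * aspects[idx]
        theta = rng.uniform(0.0, math.pi)
        value = float(
            np.clip(
                rng.normal(spec.aggregate_intensity_mean, spec.aggregate_intensity_sd),
                0,
                2**spec.bit_depth - 1,
            )
        )
        if spec.rim_only:
            bands = [
                (inner_top + a, top + rim_px - a),
                (top + width_px - rim_px + a, inner_bot - a),
            ]
            bands = [bd for bd in bands if bd[0] < bd[1]]
            if not bands:
                raise ValueError(
                    f"aggregate of {areas[idx]:.0f} um^2 does not fit in the "
                    f"{spec.rim_um} um rim band"
                )
        else:
            bands = [(inner_top + a, inner_bot - a)]
        for attempt in range(1000):
            r_lo, r_hi = bands[rng.integers(len(bands))] if len(bands) > 1 else bands[0]
            row = rng.uniform(r_lo, r_hi)
            col = rng.uniform(a + 2, ncol - a - 2)
            if all(
                math.hypot(row - r2, col - c2) > a + a2 + 2 for r2, c2, a2, *_ in placed
            ):
                placed.append((row, col, a, b, theta, value))
                break
        else:
            raise ValueError(
                f"could not place aggregate {idx} without overlap after 1000 "
                "attempts; the fixture spec is too dense"
            )
    return placed


def _render_scene(
    spec: FixtureSpec, blobs: list[tuple], alpha_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render the noise-free scene and the crisp blob mask at angle ``alpha_deg``.

    The scene is drawn directly in the rotated frame — wall lines as tilted
    bands, blobs as ellipses with rotated centres and orientations — the way
    a camera samples an optically misaligned channel.  Rendering analytically
    (rather than resampling an aligned rendering) keeps the noise statistics
    stationary and the edges free of interpolation artefacts.
    """
    nrow, ncol = spec.image_shape
    px = spec.pixel_size_um
    top = int(round(spec.top_wall_row))
    width_px = int(round(spec.channel_width_um / px))
    alpha = math.radians(alpha_deg)
    cos_a, sin_a, tan_a = math.cos(alpha), math.sin(alpha), math.tan(alpha)
    r_mid, c_mid = (nrow - 1) / 2.0, (ncol - 1) / 2.0

    cols = np.arange(ncol, dtype=float)
    rows = np.arange(nrow, dtype=float)[:, None]

    def wall_line(r0: float) -> np.ndarray:
        return r_mid + (r0 - r_mid) / cos_a + tan_a * (cols - c_mid)

    top_line = wall_line(float(top))
    bot_line = wall_line(float(top + width_px))
    canvas = np.full(spec.image_shape, spec.background_mean, dtype=float)
    canvas[(rows >= top_line) & (rows < bot_line)] += spec.interior_offset
    wall_band = (np.abs(rows - top_line) <= _WALL_HALF_THICKNESS) | (
        np.abs(rows - bot_line) <= _WALL_HALF_THICKNESS
    )
    canvas[wall_band] = spec.wall_intensity

    truth = np.zeros(spec.image_shape, dtype=bool)
    for row, col, a, b, theta, value in blobs:
        dr, dc = row - r_mid, col - c_mid
        row_r = r_mid + cos_a * dr + sin_a * dc
        col_r = c_mid - sin_a * dr + cos_a * dc
        rr, cc = _sk_ellipse(
            row_r, col_r, a, b, shape=spec.image_shape, rotation=theta - alpha
        )
        truth[rr, cc] = True
        canvas[rr, cc] = value
    return canvas, truth


def generate(spec: FixtureSpec, condition: str = "activated") -> Fixture:
    """Render a synthetic channel image and its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.image_shape
    px = spec.pixel_size_um
    top = int(round(spec.top_wall_row))
    width_px = int(round(spec.channel_width_um / px))
    if top - _WALL_HALF_THICKNESS < 0 or top + width_px + _WALL_HALF_THICKNESS + 1 > nrow:
        raise ValueError("channel band (with walls) does not fit in the raster")

    blobs = _sample_blobs(spec, rng) if spec.n_aggregates > 0 else []
    alpha = spec.true_alpha_deg
    canvas, truth_rot = _render_scene(spec, blobs, alpha)
    if alpha != 0.0:
        _, truth_aligned = _render_scene(spec, blobs, 0.0)
    else:
        truth_aligned = truth_rot

    if spec.edge_blur_sigma_px > 0:
        canvas = gaussian_filter(canvas, spec.edge_blur_sigma_px)
    canvas = canvas + rng.normal(0.0, spec.background_sd, spec.image_shape)

    max_value = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(canvas), 0, max_value).astype(dtype)
    image = ImageGrid(pixels, spec.bit_depth, px, name=f"synthetic_seed{spec.seed}")

    half_span = (ncol - 1) / 2.0 * math.tan(math.radians(alpha))
    row_mid_adjusted = (nrow - 1) / 2.0 + (
        spec.top_wall_row - (nrow - 1) / 2.0
    ) / math.cos(math.radians(alpha))
    geometry = ChannelGeometry(
        alpha_deg=alpha,
        top_wall_row_left=row_mid_adjusted - half_span,
        top_wall_row_right=row_mid_adjusted + half_span,
        channel_width_um=spec.channel_width_um,
        rim_um=spec.rim_um,
    )
    return Fixture(
        spec=spec,
        image=image,
        truth_mask=BinaryMask(truth_rot, px, provenance="synthetic_truth"),
        truth_mask_aligned=BinaryMask(truth_aligned, px, provenance="synthetic_truth"),
        geometry=geometry,
        condition=condition,
    )


def rim_only_spec(seed: int = 0, **overrides) -> FixtureSpec:
    """Spec with all aggregates confined to the 50 µm near-wall rim."""
    params = dict(
        seed=seed,
        rim_only=True,
        true_alpha_deg=1.5,
        n_aggregates=30,
        aggregate_area_um2_range=(100.0, 600.0),
    )
    params.update(overrides)
    return FixtureSpec(**params)


def fixture_suite(
    n_images: int = 10, base_seed: int = 1, condition_mix: float = 0.5
) -> list[Fixture]:
    """A validation suite of fixtures spanning sparse to dense coverage.

    ``condition_mix`` is the fraction of "activated" fixtures.  Untreated
    fixtures carry 0-5 small aggregates (coverage well under half a
    percent); activated fixtures carry 25-50 large aggregates (coverage of
    a few to a few tens of percent).  Each fixture also receives a random
    misalignment angle in ±3°.  Seeds are ``base_seed*1000 + index``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not (0.0 <= condition_mix <= 1.0):
        raise ValueError("condition_mix must be in [0, 1]")
    n_activated = int(round(n_images * condition_mix))
    fixtures = []
    for i in range(n_images):
        seed = base_seed * 1000 + i
        rng = np.random.default_rng(seed + 500_000)
        alpha = float(rng.uniform(-3.0, 3.0))
        activated = i < n_activated
        if activated:
            spec = FixtureSpec(
                seed=seed,
                true_alpha_deg=alpha,
                n_aggregates=int(rng.integers(25, 51)),
                aggregate_area_um2_range=(300.0, 3000.0),
            )
        else:
            spec = FixtureSpec(
                seed=seed,
                true_alpha_deg=alpha,
                n_aggregates=int(rng.integers(0, 6)),
                aggregate_area_um2_range=(25.0, 64.0),
            )
        fixtures.append(generate(spec, condition="activated" if activated else "untreated"))
    return fixtures
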