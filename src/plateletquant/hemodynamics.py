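"""Wall shear rate in a rectangular microfluidic duct.

Two levels of description are provided:

* The **parallel-plate relation** γ = 6Q/(w·h²), which sets the syringe-pump
  flow rate Q for a target wall shear rate γ in a wide, shallow channel of
  width w and height h.  For the device used here (w = 300 µm, h = 51 µm) a
  target of 1000 s⁻¹ — an arterial shear rate — requires ≈ 7.8 µL/min.

* The **exact series solution** for fully developed, incompressible laminar
  flow in a rectangular duct with no-slip walls.  The lateral profile of the
  bottom-wall shear rate shows the side-wall "edge effect": shear vanishes
  at the side walls and plateaus in the middle.  This is the quantitative
  basis for insetting the analysis region 50 µm from the side walls, where
  the local shear is still ≥ 95% of the centreline value.

The velocity field for a duct occupying 0 ≤ y ≤ w (width) and 0 ≤ z ≤ h
(height) under a pressure gradient G = −dp/dx is

    u(y, z) = (4 G h² / π³ μ) Σ_{n odd} n⁻³ [1 − cosh(nπ(y−w/2)/h) /
              cosh(nπw/2h)] sin(nπ z/h),

whose bottom-wall shear rate γ(y) = ∂u/∂z |_{z=0} follows term by term.  The
odd-harmonic sum Σ n⁻² is evaluated in closed form (π²/8) so the truncation
error of the remaining exponentially decaying sum is negligible already at
tens of terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlowSpec",
    "ShearProfile",
    "flow_for_shear",
    "shear_for_flow",
    "duct_shear_profile",
    "ul_min_to_m3_s",
    "m3_s_to_ul_min",
]

_PI = np.pi


def ul_min_to_m3_s(q_ul_min: float) -> float:
    return q_ul_min * 1e-9 / 60.0


def m3_s_to_ul_min(q_m3_s: float) -> float:
    return q_m3_s * 1e9 * 60.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def flow_for_shear(gamma_s1: float, width_m: float, height_m: float) -> float:
    """Volumetric flow Q (m³/s) producing wall shear rate γ: Q = γ·w·h²/6."""
    _require_positive(gamma_s1=gamma_s1, width_m=width_m, height_m=height_m)
    return gamma_s1 * width_m * height_m**2 / 6.0


def shear_for_flow(q_m3_s: float, width_m: float, height_m: float) -> float:
    """Parallel-plate wall shear rate γ = 6Q/(w·h²) in s⁻¹."""
    _require_positive(q_m3_s=q_m3_s, width_m=width_m, height_m=height_m)
    return 6.0 * q_m3_s / (width_m * height_m**2)


@dataclass(frozen=True)
class FlowSpec:
    """A consistent (γ, Q, w, h) quadruple under γ = 6Q/(w·h²)."""

    gamma_s1: float
    q_m3_s: float
    width_m: float
    height_m: float

    def __post_init__(self) -> None:
        _require_positive(
            gamma_s1=self.gamma_s1, q_m3_s=self.q_m3_s,
            width_m=self.width_m, height_m=self.height_m,
        )
        implied = shear_for_flow(self.q_m3_s, self.width_m, self.height_m)
        if abs(implied - self.gamma_s1) > 1e-9 * self.gamma_s1:
            raise ValueError(
                f"inconsistent flow spec: gamma={self.gamma_s1} s^-1 but "
                f"6Q/(w h^2)={implied} s^-1"
            )

    @classmethod
    def from_shear(cls, gamma_s1: float, width_m: float, height_m: float) -> "FlowSpec":
        return cls(gamma_s1, flow_for_shear(gamma_s1, width_m, height_m),
                   width_m, height_m)

    @classmethod
    def from_flow(cls, q_m3_s: float, width_m: float, height_m: float) -> "FlowSpec":
        return cls(shear_for_flow(q_m3_s, width_m, height_m), q_m3_s,
                   width_m, height_m)

    @property
    def q_ul_min(self) -> float:
        return m3_s_to_ul_min(self.q_m3_s)


@dataclass
class ShearProfile:
    """Bottom-wall shear rate across the channel width."""

    lateral_positions_um: np.ndarray
    shear_s1: np.ndarray
    n_terms: int

    @property
    def centerline_shear_s1(self) -> float:
        return float(self.shear_s1[np.argmin(
            np.abs(self.lateral_positions_um - self.lateral_positions_um[-1] / 2)
        )])

    @property
    def max_shear_s1(self) -> float:
        return float(self.shear_s1.max())

    def pct_of_max_at(self, distance_from_wall_um: float) -> float:
        """Shear at a given distance from the nearer side wall, in % of max.

        Both side walls are checked and the smaller percentage is returned.
        """
        w_um = float(self.lateral_positions_um[-1])
        vals = np.interp(
            [distance_from_wall_um, w_um - distance_from_wall_um],
            self.lateral_positions_um, self.shear_s1,
        )
        return float(vals.min() / self.max_shear_s1 * 100.0)


def _wall_shear_shape(
    y_m: np.ndarray, width_m: float, height_m: float, n_terms: int
) -> np.ndarray:
    """γ(y) for unit G/μ: (4h/π²)[π²/8 − Σ_odd n⁻² cosh(nπy_c/h)/cosh(nπw/2h)].

    The cosh ratio is evaluated as exp(a−b)(1+e^{−2a})/(1+e^{−2b}) to avoid
    overflow.  Positions exactly at a side wall return 0 (the analytical
    limit).
    """
    y = np.atleast_1d(np.asarray(y_m, dtype=float))
    yc = np.abs(y - width_m / 2.0)
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    a = _PI * np.outer(n, yc) / height_m
    b = (_PI * n * width_m / (2.0 * height_m))[:, None]
    ratio = np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))
    s = ((1.0 / n**2)[:, None] * ratio).sum(axis=0)
    shape = (4.0 * height_m / _PI**2) * (_PI**2 / 8.0 - s)
    shape[np.isclose(yc, width_m / 2.0)] = 0.0
    return shape


def _flow_factor(width_m: float, height_m: float, n_terms: int) -> float:
    """Q/(G/μ) for the rectangular duct (the classic tanh series)."""
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    series = np.sum(np.tanh(n * _PI * width_m / (2.0 * height_m)) / n**5)
    return (height_m**3 * width_m / 12.0) * (
        1.0 - (192.0 * height_m / (_PI**5 * width_m)) * series
    )


def duct_shear_profile(
    q_m3_s: float,
    width_m: float,
    height_m: float,
    n_terms: int = 200,
    n_points: int = 601,
) -> ShearProfile:
    """Bottom-wall shear-rate profile of a rectangular duct at flow rate Q.

    The series solution is scaled so the cross-section integral of the
    velocity equals Q.  ``n_terms`` is the number of odd harmonics retained;
    convergence is checked by comparing against a doubled truncation at the
    centreline (error if the relative change exceeds 0.1%).
    """
    _require_positive(q_m3_s=q_m3_s, width_m=width_m, height_m=height_m)
    if width_m < height_m:
        raise ValueError("expected wide-channel orientation (width >= height)")
    if n_terms < 50:
        raise ValueError("n_terms must be >= 50")
    center = np.array([width_m / 2.0])
    ref = _wall_shear_shape(center, width_m, height_m, n_terms)[0]
    ref2 = _wall_shear_shape(center, width_m, height_m, 2 * n_terms)[0]
    if abs(ref2 - ref) > 1e-3 * ref2:
        raise ValueError(f"series not converged at n_terms={n_terms}")
    g_over_mu = q_m3_s / _flow_factor(width_m, height_m, n_terms)
    y = np.linspace(0.0, width_m, n_points)
    shear = g_over_mu * _wall_shear_shape(y, width_m, height_m, n_terms)
    return ShearProfile(
        lateral_positions_um=y * 1e6,
        shear_s1=shear,
        n_terms=n_terms,
    )
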