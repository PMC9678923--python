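"""Closed-form canopy airflow attenuation and drag equations.

The in-canopy airflow velocity decays exponentially with depth,
``v(y) = v* exp(-k y)``, where ``k`` (1/m) is the velocity attenuation
factor.  Integrating the aerodynamic drag on the foliage over the
cylindrical air-assisted region yields a closed-form canopy resistance

    F(k) = s * rho * v*^2 * (1 - exp(-2 k D)) / (4 k D')

which is strictly decreasing in ``k``; measuring F therefore determines
``k`` by bracketed 1-D root finding (:func:`solve_k`).

All quantities are strict SI: m, m/s, N, Pa, kg/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AirProperties",
    "JetGeometry",
    "CanopyLayer",
    "FlowCondition",
    "PressureDrop",
    "AttenuationFit",
    "VelocityProfile",
    "InfeasibleMeasurementError",
    "velocity_at",
    "velocity_profile",
    "dynamic_pressure",
    "drag_force",
    "windward_area_per_volume",
    "resistance_from_k",
    "resistance_from_T",
    "resistance_limit_k0",
    "solve_k",
]


class InfeasibleMeasurementError(ValueError):
    """Measured force lies outside the range attainable by any k > 0.

    Carries the k -> 0+ supremum of the resistance curve so callers can
    report how far out of range the measurement is.
    """

    def __init__(self, f_measured: float, supremum: float):
        self.f_measured = f_measured
        self.supremum = supremum
        super().__init__(
            f"measured force {f_measured} N is outside the feasible open "
            f"interval (0, {supremum:.6g}) N; no k > 0 can produce it"
        )


@dataclass(frozen=True)
class AirProperties:
    """Air density and drag coefficient entering every force formula.

    ``c_d`` defaults to 1.0 for a plane perpendicular to the flow.
    """

    rho: float = 1.29
    c_d: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"air density must be positive, got {self.rho}")
        if self.c_d <= 0:
            raise ValueError(f"drag coefficient must be positive, got {self.c_d}")


@dataclass(frozen=True)
class JetGeometry:
    """Circular air-assisted footprint of the fan jet on the canopy surface."""

    R: float = 0.16

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"jet radius must be positive, got {self.R}")


@dataclass(frozen=True)
class CanopyLayer:
    """Geometry and foliage descriptors of a canopy slab.

    Parameters
    ----------
    leaf_area_density
        One-sided leaf area per unit canopy volume Lr, m^2/m^3.
    s0
        Static (windless) windward leaf area inside the air-assisted
        area, m^2.
    D
        Depth of canopy traversed by the airflow, m.
    D_prime
        Thickness of the branch-leaf section used to normalise the
        windward area per unit volume, m.
    """

    leaf_area_density: float
    s0: float
    D: float
    D_prime: float

    def __post_init__(self) -> None:
        for name in ("leaf_area_density", "s0", "D", "D_prime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class FlowCondition:
    """Incoming flow velocity at the canopy surface, m/s."""

    v_star: float

    def __post_init__(self) -> None:
        if self.v_star < 0:
            raise ValueError(f"incoming velocity must be >= 0, got {self.v_star}")


@dataclass(frozen=True)
class PressureDrop:
    """Stagnation minus free-stream static pressure (dynamic pressure)."""

    p0: float
    p: float

    @property
    def dp(self) -> float:
        return self.p - self.p0


@dataclass(frozen=True)
class AttenuationFit:
    """An estimated attenuation factor with the condition it was fitted at."""

    k: float
    v_star: float
    layer: CanopyLayer
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"attenuation factor must be positive, got {self.k}")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


@dataclass(frozen=True)
class VelocityProfile:
    """Velocities at ordered depths from the windward canopy surface."""

    depths: np.ndarray
    velocities: np.ndarray

    def __init__(self, depths: Sequence[float], velocities: Sequence[float]):
        d = np.asarray(depths, dtype=float)
        v = np.asarray(velocities, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or d.shape != v.shape:
            raise ValueError("depths and velocities must be 1-D and equal length")
        if d.size == 0:
            raise ValueError("profile must contain at least one depth")
        if np.any(d < 0):
            raise ValueError("depths must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        d.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "velocities", v)

    def __len__(self) -> int:
        return int(self.depths.size)


def velocity_at(cond: FlowCondition, k: float, y: float) -> float:
    """Velocity at depth ``y`` inside the canopy: v* exp(-k y)."""
    if y < 0:
        raise ValueError(f"depth must be >= 0, got {y}")
    if k < 0:
        raise ValueError(f"attenuation factor must be >= 0, got {k}")
    return cond.v_star * math.exp(-k * y)


def velocity_profile(
    cond: FlowCondition, k: float, depths: Sequence[float]
) -> VelocityProfile:
    """Element-wise :func:`velocity_at` over an increasing depth grid."""
    if k < 0:
        raise ValueError(f"attenuation factor must be >= 0, got {k}")
    d = np.asarray(depths, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("depths must be a non-empty 1-D sequence")
    if np.any(d < 0) or np.any(np.diff(d) <= 0):
        raise ValueError("depths must be non-negative and strictly increasing")
    return VelocityProfile(d, cond.v_star * np.exp(-k * d))


def dynamic_pressure(air: AirProperties, v: float) -> PressureDrop:
    """Stagnation dynamic pressure dp = rho v^2 / 2 (free stream taken at 0 Pa)."""
    if v < 0:
        raise ValueError(f"velocity must be >= 0, got {v}")
    return PressureDrop(p0=0.0, p=0.5 * air.rho * v * v)


def drag_force(air: AirProperties, v: float, s_windward: float) -> float:
    """Aerodynamic drag on a windward area: F = C_d rho v^2 S / 2."""
    if v < 0:
        raise ValueError(f"velocity must be >= 0, got {v}")
    if s_windward < 0:
        raise ValueError(f"windward area must be >= 0, got {s_windward}")
    return 0.5 * air.c_d * air.rho * v * v * s_windward


def windward_area_per_volume(s: float, jet: JetGeometry, d_prime: float) -> float:
    """Windward area per unit canopy volume: T = s / (pi R^2 D')."""
    if s <= 0:
        raise ValueError(f"windward area must be positive, got {s}")
    if d_prime <= 0:
        raise ValueError(f"section thickness must be positive, got {d_prime}")
    return s / (math.pi * jet.R**2 * d_prime)


def resistance_from_k(
    k: float, layer: CanopyLayer, cond: FlowCondition, air: AirProperties
) -> float:
    """Canopy resistance F(k) = C_d s rho v*^2 (1 - e^(-2kD)) / (4 k D').

    Strictly decreasing in k; use :func:`resistance_limit_k0` for the
    k -> 0+ limit rather than evaluating the 0/0 form here.
    """
    if k <= 0:
        raise ValueError(
            f"attenuation factor must be positive, got {k}; "
            "use resistance_limit_k0 for k = 0"
        )
    return (
        air.c_d
        * layer.s0
        * air.rho
        * cond.v_star**2
        * -math.expm1(-2.0 * k * layer.D)
        / (4.0 * k * layer.D_prime)
    )


def resistance_from_T(
    k: float,
    T: float,
    jet: JetGeometry,
    d: float,
    cond: FlowCondition,
    air: AirProperties,
) -> float:
    """Resistance expressed through the per-volume windward area T.

    F = C_d pi R^2 T rho v*^2 (1 - e^(-2kD)) / (4k); algebraically
    identical to :func:`resistance_from_k` when T = s / (pi R^2 D').
    """
    if k <= 0:
        raise ValueError(f"attenuation factor must be positive, got {k}")
    if T <= 0:
        raise ValueError(f"windward area per volume must be positive, got {T}")
    if d <= 0:
        raise ValueError(f"depth must be positive, got {d}")
    return (
        air.c_d
        * math.pi
        * jet.R**2
        * T
        * air.rho
        * cond.v_star**2
        * -math.expm1(-2.0 * k * d)
        / (4.0 * k)
    )


def resistance_limit_k0(
    layer: CanopyLayer, cond: FlowCondition, air: AirProperties
) -> float:
    """Supremum of F(k) as k -> 0+: C_d s rho v*^2 D / (2 D')."""
    return (
        air.c_d
        * layer.s0
        * air.rho
        * cond.v_star**2
        * layer.D
        / (2.0 * layer.D_prime)
    )


def solve_k(
    f_measured: float,
    layer: CanopyLayer,
    cond: FlowCondition,
    air: AirProperties | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> AttenuationFit:
    """Invert the resistance curve for the attenuation factor k.

    F(k) is continuous and strictly decreasing from the k -> 0+ supremum
    to 0, so any measured force in that open interval has a unique root.
    The bracket starts at [1e-9, 1] and the upper end is grown
    geometrically until the sign changes, then Brent's method polishes
    the root to relative tolerance ``tol``.

    Raises
    ------
    InfeasibleMeasurementError
        If ``f_measured`` is not strictly inside (0, supremum).
    """
    if air is None:
        air = AirProperties()
    supremum = resistance_limit_k0(layer, cond, air)
    if not (0.0 < f_measured < supremum):
        raise InfeasibleMeasurementError(f_measured, supremum)

    def objective(k: float) -> float:
        return resistance_from_k(k, layer, cond, air) - f_measured

    lo, hi = 1e-9, 1.0
    grow = 0
    while objective(hi) > 0.0:
        hi *= 2.0
        grow += 1
        if grow > 60:  # F(k) ~ C/k, so 2^60 is unreachable for feasible F
            raise RuntimeError("failed to bracket the attenuation factor")
    k = brentq(objective, lo, hi, rtol=tol, maxiter=max_iter)
    residual = abs(resistance_from_k(k, layer, cond, air) - f_measured)
    return AttenuationFit(k=k, v_star=cond.v_star, layer=layer, residual=residual)
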