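"""Dynamic windward-area correction for the outer canopy layer.

High-speed airflow folds the outer (0-0.3 m) foliage together, shrinking
its windward area from the static (windless) value ``s0`` down to a
saturation value ``s_min`` reached at the saturation velocity ``v_sat``.
The corrected resistance model replaces s0 with the velocity-dependent
s*(v*) for that outer layer only; deeper layers keep the static area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    AirProperties,
    AttenuationFit,
    CanopyLayer,
    FlowCondition,
    VelocityProfile,
    solve_k,
)

__all__ = [
    "DynamicWindwardModel",
    "TwoLayerCanopy",
    "fit_dynamic_windward",
    "s_star_at",
    "corrected_solve_k",
    "two_layer_profile",
]

#: relative decrease between successive anchors below which s*(v) is
#: considered to have plateaued
PLATEAU_RTOL = 0.01


@dataclass(frozen=True)
class DynamicWindwardModel:
    """Monotone piecewise-linear model of the dynamic windward area s*(v*).

    Clamped to ``s0`` below the first anchor and to ``s_min`` at and
    beyond the saturation velocity ``v_sat``.
    """

    s0: float
    anchor_v: np.ndarray
    anchor_s: np.ndarray
    v_sat: float
    s_min: float

    def __call__(self, v_star: float) -> float:
        return s_star_at(self, v_star)


@dataclass(frozen=True)
class TwoLayerCanopy:
    """Outer layer (dynamic s*) stacked on an inner layer (static s0)."""

    outer: CanopyLayer
    inner: CanopyLayer
    boundary: float = 0.3

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError(f"layer boundary must be positive, got {self.boundary}")
        if not np.isclose(self.outer.D, self.boundary):
            raise ValueError(
                f"outer layer depth {self.outer.D} must equal the boundary "
                f"{self.boundary}"
            )


def fit_dynamic_windward(
    pairs: Sequence[tuple[float, float]],
    s0: float,
    v_sat_hint: float | None = None,
) -> DynamicWindwardModel:
    """Fit the s*(v*) interpolant from measured (v*, s*) calibration pairs.

    The anchors must be non-increasing in s (a small relative increase up
    to ``PLATEAU_RTOL`` is tolerated as noise).  The saturation velocity
    is the smallest anchor velocity from which every successive relative
    decrease stays below ``PLATEAU_RTOL``, unless a hint overrides it.
    """
    if s0 <= 0:
        raise ValueError(f"static windward area must be positive, got {s0}")
    if len(pairs) < 2:
        raise ValueError("need at least two (v_star, s_star) calibration pairs")
    arr = sorted((float(v), float(s)) for v, s in pairs)
    v = np.array([p[0] for p in arr])
    s = np.array([p[1] for p in arr])
    if np.unique(v).size != v.size:
        raise ValueError("calibration pairs must have distinct v_star values")
    if np.any(s <= 0) or np.any(s > s0 * (1 + PLATEAU_RTOL)):
        raise ValueError("all s_star must lie in (0, s0]")
    rel_change = np.diff(s) / s[:-1]
    if np.any(rel_change > PLATEAU_RTOL):
        raise ValueError("s_star must be non-increasing in v_star (beyond 1% tolerance)")
    # enforce exact monotonicity for the interpolant
    s = np.minimum.accumulate(np.minimum(s, s0))

    if v_sat_hint is not None:
        v_sat = float(v_sat_hint)
    else:
        # smallest v after which the relative decrease per step stays < tol
        v_sat = v[-1]
        for i in range(len(v)):
            tail = -rel_change[i:] if i < len(rel_change) else np.array([])
            if tail.size == 0 or np.all(tail < PLATEAU_RTOL):
                v_sat = v[i]
                break
    s_min = float(np.interp(v_sat, v, s))
    return DynamicWindwardModel(s0=s0, anchor_v=v, anchor_s=s, v_sat=v_sat, s_min=s_min)


def s_star_at(model: DynamicWindwardModel, v_star: float) -> float:
    """Evaluate the dynamic windward area at a given incoming velocity."""
    if v_star < 0:
        raise ValueError(f"incoming velocity must be >= 0, got {v_star}")
    if v_star >= model.v_sat:
        return model.s_min
    if v_star <= model.anchor_v[0]:
        # linear ramp from the windless s0 at v = 0 to the first anchor
        v0, s0v = model.anchor_v[0], model.anchor_s[0]
        return float(model.s0 + (s0v - model.s0) * v_star / v0)
    return float(np.interp(v_star, model.anchor_v, model.anchor_s))


def corrected_solve_k(
    f_measured: float,
    two_layer: TwoLayerCanopy,
    cond: FlowCondition,
    air: AirProperties,
    model: DynamicWindwardModel,
) -> AttenuationFit:
    """Solve for k with the outer-layer windward area replaced by s*(v*).

    A layer no deeper than the two-layer boundary uses the dynamic area;
    anything deeper keeps the static s0 and the fit reduces to the
    uncorrected solve.
    """
    outer = two_layer.outer
    if outer.D <= two_layer.boundary + 1e-12:
        s_eff = s_star_at(model, cond.v_star)
        layer = CanopyLayer(
            leaf_area_density=outer.leaf_area_density,
            s0=s_eff,
            D=outer.D,
            D_prime=outer.D_prime,
        )
    else:
        layer = outer
    return solve_k(f_measured, layer, cond, air)


def two_layer_profile(
    cond: FlowCondition,
    k_outer: float,
    k_inner: float,
    depths: Sequence[float],
    boundary: float = 0.3,
) -> VelocityProfile:
    """Piecewise-exponential profile with separate outer/inner attenuation.

    v(y) = v* e^(-k_outer y) for y <= boundary, then decays further with
    k_inner; continuous at the boundary because exponential attenuation
    is memoryless in depth.
    """
    if k_outer < 0 or k_inner < 0:
        raise ValueError("attenuation factors must be >= 0")
    if boundary <= 0:
        raise ValueError(f"layer boundary must be positive, got {boundary}")
    d = np.asarray(depths, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("depths must be a non-empty 1-D sequence")
    if np.any(d < 0) or np.any(np.diff(d) <= 0):
        raise ValueError("depths must be non-negative and strictly increasing")
    if k_outer == k_inner:
        # degenerate composition collapses to the single-layer profile
        return VelocityProfile(d, cond.v_star * np.exp(-k_outer * d))
    v = np.where(
        d <= boundary,
        cond.v_star * np.exp(-k_outer * d),
        cond.v_star * np.exp(-k_outer * boundary) * np.exp(-k_inner * (d - boundary)),
    )
    return VelocityProfile(d, v)
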