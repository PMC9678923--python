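"""Seeded generators emulating the drag/velocity measurement campaigns.

Instrument noise follows the hardware specs of the original campaigns:
the force gauge has a relative indication error of +/-0.5% (a maximum
permissible error, modelled as uniform within the bound) and the
anemometer reads within +/-0.025 m/s (a repeatability figure, modelled
as Gaussian with that sd).  Every generator is a pure function of its
arguments and seed, and always emits the hidden ground truth next to the
noisy observations so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AirProperties,
    CanopyLayer,
    FlowCondition,
    JetGeometry,
    VelocityProfile,
    resistance_from_k,
    velocity_at,
)
from .imaging import ProjectionImage

__all__ = [
    "CampaignSpec",
    "SyntheticCampaign",
    "generate_campaign",
    "generate_velocity_measurements",
    "generate_canopy_image",
]

CAMPAIGN_COLUMNS = [
    "leaf_area_density",
    "v_star",
    "force_N",
    "s_m2",
    "R_m",
    "D_m",
    "D_prime_m",
]


@dataclass(frozen=True)
class CampaignSpec:
    """Grid of (density, incoming velocity) conditions with hidden truth.

    ``true_k`` maps (Lr, v*) to the attenuation factor the forces are
    generated from; ``s_by_density`` gives the windward area per Lr.
    """

    densities: tuple[float, ...]
    v_stars: tuple[float, ...]
    true_k: Mapping[tuple[float, float], float]
    s_by_density: Mapping[float, float]
    jet: JetGeometry = JetGeometry()
    air: AirProperties = AirProperties()
    D: float = 0.9
    D_prime: float = 0.3
    force_noise_rel: float = 0.005
    anemometer_sd: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.densities or not self.v_stars:
            raise ValueError("density and velocity grids must be non-empty")
        if self.force_noise_rel < 0 or self.anemometer_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for cell in ((lr, v) for lr in self.densities for v in self.v_stars):
            if cell not in self.true_k:
                raise ValueError(f"true_k missing grid cell {cell}")
            if self.true_k[cell] <= 0:
                raise ValueError(f"true_k must be positive at {cell}")


@dataclass(frozen=True)
class SyntheticCampaign:
    """Observed campaign table plus the hidden truth it was drawn from."""

    observations: pd.DataFrame  # CAMPAIGN_COLUMNS
    truth: pd.DataFrame  # leaf_area_density, v_star, true_k, force_true_N
    seed: int


def generate_campaign(spec: CampaignSpec) -> SyntheticCampaign:
    """Draw one noisy campaign table from the spec.

    Forces are truth * (1 + U(-b, b)) with b = force_noise_rel, matching
    the gauge's maximum-permissible indication error; non-positive draws
    (only possible for b >= 1) are rejected and resampled.
    """
    rng = np.random.default_rng(spec.seed)
    obs_rows, truth_rows = [], []
    for lr in spec.densities:
        s = spec.s_by_density[lr]
        layer = CanopyLayer(
            leaf_area_density=lr, s0=s, D=spec.D, D_prime=spec.D_prime
        )
        for v in spec.v_stars:
            k = spec.true_k[(lr, v)]
            f_true = resistance_from_k(k, layer, FlowCondition(v), spec.air)
            b = spec.force_noise_rel
            f_obs = f_true * (1.0 + rng.uniform(-b, b)) if b > 0 else f_true
            while f_obs <= 0.0:
                f_obs = f_true * (1.0 + rng.uniform(-b, b))
            obs_rows.append(
                {
                    "leaf_area_density": lr,
                    "v_star": v,
                    "force_N": f_obs,
                    "s_m2": s,
                    "R_m": spec.jet.R,
                    "D_m": spec.D,
                    "D_prime_m": spec.D_prime,
                }
            )
            truth_rows.append(
                {
                    "leaf_area_density": lr,
                    "v_star": v,
                    "true_k": k,
                    "force_true_N": f_true,
                }
            )
    return SyntheticCampaign(
        observations=pd.DataFrame(obs_rows, columns=CAMPAIGN_COLUMNS),
        truth=pd.DataFrame(truth_rows),
        seed=spec.seed,
    )


def generate_velocity_measurements(
    k: float,
    cond: FlowCondition,
    depths: Sequence[float],
    sd: float = 0.025,
    seed: int = 0,
) -> VelocityProfile:
    """Noisy anemometer readings of an exponential profile, floored at 0."""
    if sd < 0:
        raise ValueError(f"anemometer sd must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    d = np.asarray(depths, dtype=float)
    truth = np.array([velocity_at(cond, k, y) for y in d])
    noisy = np.maximum(truth + rng.normal(0.0, sd, size=d.shape), 0.0)
    return VelocityProfile(d, noisy)


def generate_canopy_image(
    leaf_fraction_target: float,
    roi_radius_px: int = 120,
    image_size: tuple[int, int] = (300, 300),
    seed: int = 0,
) -> tuple[ProjectionImage, float]:
    """White-background image with dark ellipses covering the ROI.

    Random dark ellipses are accumulated inside the ROI circle until the
    covered fraction is within 0.5% absolute of the target; the ellipse
    size shrinks as the remaining gap closes so the target is never
    overshot by more than the tolerance.  Returns the image and the
    achieved coverage (the ground truth for round-trip tests).
    """
    if not 0.0 <= leaf_fraction_target < 1.0:
        raise ValueError(
            f"target leaf fraction must be in [0, 1), got {leaf_fraction_target}"
        )
    rng = np.random.default_rng(seed)
    nr, nc = image_size
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    if roi_radius_px > min(r0, c0):
        raise ValueError("ROI radius does not fit inside the image")

    rr, cc = np.ogrid[:nr, :nc]
    roi = (rr - r0) ** 2 + (cc - c0) ** 2 < roi_radius_px**2
    n_roi = int(roi.sum())

    leaf = np.zeros((nr, nc), dtype=bool)
    tol = 0.005
    max_draws = 20000
    for _ in range(max_draws):
        cov = leaf[roi].sum() / n_roi
        gap = leaf_fraction_target - cov
        if gap <= tol / 2.0:
            break
        # ellipse sized so its ROI footprint cannot overshoot past the target
        max_area_px = max(gap * n_roi, 12.0)
        a = min(np.sqrt(max_area_px / np.pi), 0.25 * roi_radius_px)
        a = max(a, 1.5)
        b = a * rng.uniform(0.4, 1.0)
        theta = rng.uniform(0.0, np.pi)
        rad = rng.uniform(0.0, roi_radius_px)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        er, ec = r0 + rad * np.sin(ang), c0 + rad * np.cos(ang)
        ct, st = np.cos(theta), np.sin(theta)
        u = (rr - er) * ct + (cc - ec) * st
        w = -(rr - er) * st + (cc - ec) * ct
        leaf |= (u / a) ** 2 + (w / b) ** 2 <= 1.0
    achieved = float(leaf[roi].sum() / n_roi)
    if abs(achieved - leaf_fraction_target) > tol:
        raise RuntimeError(
            f"coverage {achieved:.4f} did not converge to target "
            f"{leaf_fraction_target:.4f} within {tol}"
        )

    pixels = np.full((nr, nc), 255.0)
    pixels[leaf] = rng.uniform(10.0, 60.0, size=int(leaf.sum()))
    # metric scale chosen so the ROI radius maps to the default jet radius
    scale = JetGeometry().R / roi_radius_px
    img = ProjectionImage(
        pixels=pixels, scale=scale, roi_center=(r0, c0), roi_radius_px=roi_radius_px
    )
    return img, achieved
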