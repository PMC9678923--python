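"""Windward leaf area from white-background canopy projection photographs.

The canopy is photographed along the jet axis against a white cloth with
the circular air-assisted area marked on it.  Dark pixels inside that
circle are foliage; their fraction times the metric circle area gives
the windward leaf area s.  Overlapping leaves project to a single
coverage — no depth disambiguation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import JetGeometry, windward_area_per_volume

__all__ = [
    "ProjectionImage",
    "WindwardAreaEstimate",
    "estimate_windward_area",
    "area_to_T",
    "load_projection_image",
]


@dataclass(frozen=True)
class ProjectionImage:
    """Grayscale projection photo with the marked circular ROI.

    ``scale`` is metres per pixel; the ROI circle must lie fully inside
    the image bounds.
    """

    pixels: np.ndarray
    scale: float
    roi_center: tuple[float, float]  # (row, col), px
    roi_radius_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grayscale array")
        object.__setattr__(self, "pixels", px)
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.roi_radius_px <= 0:
            raise ValueError("ROI radius must be positive")
        r0, c0 = self.roi_center
        nr, nc = px.shape
        if (
            r0 - self.roi_radius_px < 0
            or c0 - self.roi_radius_px < 0
            or r0 + self.roi_radius_px > nr - 1
            or c0 + self.roi_radius_px > nc - 1
        ):
            raise ValueError("ROI circle extends outside the image bounds")

    @property
    def roi_radius_m(self) -> float:
        return self.roi_radius_px * self.scale

    def roi_mask(self) -> np.ndarray:
        rr, cc = np.ogrid[: self.pixels.shape[0], : self.pixels.shape[1]]
        r0, c0 = self.roi_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 < self.roi_radius_px**2


@dataclass(frozen=True)
class WindwardAreaEstimate:
    leaf_fraction: float
    s: float  # m^2
    threshold_used: float
    low_confidence: bool = False


def estimate_windward_area(
    img: ProjectionImage, threshold: float | None = None
) -> WindwardAreaEstimate:
    """Classify sub-threshold ROI pixels as leaf and convert to area.

    When no threshold is supplied an Otsu threshold is computed from the
    ROI pixels alone; a degenerate (uniform) ROI falls back to the
    midpoint of the image dtype range and flags low confidence.
    """
    mask = img.roi_mask()
    roi = img.pixels[mask]
    low_confidence = False
    if threshold is None:
        if np.ptp(roi) == 0:
            # uniform ROI: midpoint of the intensity scale (0-1 or 0-255)
            threshold = 0.5 if roi.max() <= 1.0 else 127.5
            low_confidence = True
        else:
            threshold = float(threshold_otsu(roi))
    leaf_fraction = float(np.mean(roi < threshold))
    s = leaf_fraction * np.pi * img.roi_radius_m**2
    return WindwardAreaEstimate(
        leaf_fraction=leaf_fraction,
        s=float(s),
        threshold_used=float(threshold),
        low_confidence=low_confidence,
    )


def area_to_T(
    est: WindwardAreaEstimate,
    img: ProjectionImage,
    jet: JetGeometry,
    d_prime: float,
) -> float:
    """Normalise the estimated area by the air-assisted cylinder volume.

    The metric ROI radius must agree with the jet radius within 1%,
    otherwise the pixel scale is miscalibrated.
    """
    if abs(img.roi_radius_m - jet.R) > 0.01 * jet.R:
        raise ValueError(
            f"ROI metric radius {img.roi_radius_m:.4g} m disagrees with jet "
            f"radius {jet.R:.4g} m by more than 1%; check the pixel scale"
        )
    if est.s == 0.0:
        return 0.0
    return windward_area_per_volume(est.s, jet, d_prime)


def load_projection_image(
    path: str,
    scale: float,
    roi_center: tuple[float, float],
    roi_radius_px: float,
) -> ProjectionImage:
    """Read a PNG/JPEG as grayscale and wrap it with ROI metadata."""
    from PIL import Image

    with Image.open(path) as im:
        px = np.asarray(im.convert("L"), dtype=float)
    return ProjectionImage(
        pixels=px, scale=scale, roi_center=roi_center, roi_radius_px=roi_radius_px
    )
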