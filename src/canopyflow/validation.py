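"""Agreement metrics between theoretical and experimental velocity profiles.

Per-point error v_w = |v2 - v1| and accuracy I = (1 - v_w/v1) * 100 %,
where v1 is the theoretical and v2 the experimental velocity.  The
accuracy divides by the theoretical value and is reported as computed —
it can go negative when the error exceeds v1; means never clamp it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import VelocityProfile

__all__ = [
    "ValidationRecord",
    "ValidationReport",
    "score_point",
    "score_profiles",
    "mean_relative_error",
    "aggregate_accuracy",
]


@dataclass(frozen=True)
class ValidationRecord:
    y: float
    v1: float  # theoretical m/s
    v2: float  # experimental m/s
    v_w: float  # absolute error m/s
    accuracy_I: float  # percent; may be negative, never above 100


@dataclass(frozen=True)
class ValidationReport:
    records: tuple[ValidationRecord, ...]
    mean_accuracy: float
    error_range: tuple[float, float]
    r_squared: float

    def to_rows(self) -> list[dict]:
        return [
            {"depth_m": r.y, "v_theory": r.v1, "v_experiment": r.v2,
             "v_w": r.v_w, "accuracy_pct": r.accuracy_I}
            for r in self.records
        ]


def score_point(v1: float, v2: float, y: float = 0.0) -> ValidationRecord:
    """Score one (theoretical, experimental) velocity pair."""
    if v1 <= 0:
        raise ValueError(f"theoretical velocity must be positive, got {v1}")
    if v2 < 0:
        raise ValueError(f"experimental velocity must be >= 0, got {v2}")
    v_w = abs(v2 - v1)
    return ValidationRecord(y=y, v1=v1, v2=v2, v_w=v_w,
                            accuracy_I=(1.0 - v_w / v1) * 100.0)


def _r_squared(v1: np.ndarray, v2: np.ndarray) -> float:
    """Squared Pearson correlation (regression of experimental on theoretical)."""
    if v1.size < 2 or np.ptp(v1) == 0 or np.ptp(v2) == 0:
        # correlation undefined for constant series; identical series agree
        return 1.0 if np.allclose(v1, v2) else 0.0
    r = np.corrcoef(v1, v2)[0, 1]
    return float(r * r)


def score_profiles(
    theoretical: VelocityProfile, experimental: VelocityProfile
) -> ValidationReport:
    """Per-depth records plus aggregate statistics for two aligned profiles."""
    if len(theoretical) != len(experimental) or not np.allclose(
        theoretical.depths, experimental.depths
    ):
        raise ValueError("profiles must share an identical depth grid")
    records = tuple(
        score_point(v1, v2, y=y)
        for y, v1, v2 in zip(
            theoretical.depths, theoretical.velocities, experimental.velocities
        )
    )
    errors = np.array([r.v_w for r in records])
    accuracies = np.array([r.accuracy_I for r in records])
    return ValidationReport(
        records=records,
        mean_accuracy=float(accuracies.mean()),
        error_range=(float(errors.min()), float(errors.max())),
        r_squared=_r_squared(theoretical.velocities, experimental.velocities),
    )


def mean_relative_error(
    series_a: Sequence[float], series_b: Sequence[float]
) -> float:
    """Mean of |a - b| / a over positions, in percent; a is the reference."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if np.any(a <= 0):
        raise ValueError("reference series must be strictly positive")
    return float(np.mean(np.abs(a - b) / a) * 100.0)


def aggregate_accuracy(
    reports: Sequence[ValidationReport],
    mode: Literal["pooled", "by_profile"] = "pooled",
) -> float:
    """Combine several reports into one mean accuracy.

    ``pooled`` averages over every point of every report; ``by_profile``
    averages the per-report means (each profile weighted equally).
    """
    if not reports:
        raise ValueError("need at least one report")
    if mode == "by_profile":
        return float(np.mean([r.mean_accuracy for r in reports]))
    if mode == "pooled":
        accs = [rec.accuracy_I for r in reports for rec in r.records]
        return float(np.mean(accs))
    raise ValueError(f"unknown aggregation mode {mode!r}")
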