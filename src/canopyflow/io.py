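"""CSV/JSON glue shared by the CLI and the fitting pipeline.

Campaign CSV dialect: comma separator, dot decimal, UTF-8, header row
with columns leaf_area_density, v_star, force_N, s_m2, R_m, D_m,
D_prime_m — one row per (density, incoming-velocity) condition.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd

from .core import AirProperties, AttenuationFit, CanopyLayer, JetGeometry

REQUIRED_COLUMNS = [
    "leaf_area_density",
    "v_star",
    "force_N",
    "s_m2",
    "R_m",
    "D_m",
    "D_prime_m",
]


class CampaignFormatError(ValueError):
    """Campaign CSV is malformed (missing columns, bad cells, no rows)."""


def read_campaign_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CampaignFormatError(
            f"campaign CSV {path} is missing required columns: {', '.join(missing)}"
        )
    if len(df) == 0:
        raise CampaignFormatError(f"campaign CSV {path} contains no rows")
    for col in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise CampaignFormatError(
                f"campaign CSV {path}: non-numeric value in column {col!r}, "
                f"row {row}"
            )
        df[col] = coerced
    return df


def reference_campaign() -> pd.DataFrame:
    """The packaged laboratory drag-campaign fixture (9 conditions)."""
    with resources.files("canopyflow.data").joinpath("lab_campaign.csv").open() as fh:
        return read_campaign_csv(fh)  # type: ignore[arg-type]


def fits_to_json(
    fits: list[AttenuationFit],
    air: AirProperties,
    jet: JetGeometry | None = None,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "air": {"rho": air.rho, "c_d": air.c_d},
        "geometry": {},
        "fits": [
            {
                "leaf_area_density": f.layer.leaf_area_density,
                "v_star": f.v_star,
                "k": f.k,
                "residual": f.residual,
                "s_m2": f.layer.s0,
                "D_m": f.layer.D,
                "D_prime_m": f.layer.D_prime,
            }
            for f in fits
        ],
    }
    if jet is not None:
        doc["geometry"]["R_m"] = jet.R
    if extra:
        doc.update(extra)
    return doc


def fits_from_json(doc: dict[str, Any]) -> list[AttenuationFit]:
    fits = []
    for f in doc["fits"]:
        layer = CanopyLayer(
            leaf_area_density=f["leaf_area_density"],
            s0=f["s_m2"],
            D=f["D_m"],
            D_prime=f["D_prime_m"],
        )
        fits.append(
            AttenuationFit(
                k=f["k"], v_star=f["v_star"], layer=layer, residual=f["residual"]
            )
        )
    return fits


def write_json(doc: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
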