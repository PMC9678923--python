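# canopyflow

Modelling airflow velocity attenuation through fruit-tree canopies for
air-assisted orchard spraying.

Airflow entering a canopy decays exponentially with depth,
`v(y) = v* exp(-k y)`, where `v*` is the incoming velocity at the canopy
surface and `k` (1/m) is the velocity attenuation factor. Integrating the
aerodynamic drag on the foliage over the circular air-assisted region gives a
closed-form canopy resistance

```
F(k) = s · ρ · v*² · (1 − e^(−2kD)) / (4 k D′)
```

with `s` the windward leaf area, `D` the traversed canopy depth, and `D′` the
thickness of the branch-leaf section. `F(k)` is strictly decreasing, so a
measured drag force determines `k` uniquely by bracketed root finding.

The package provides:

- **`canopyflow.core`** — the attenuation / drag equations and the `solve_k`
  inversion.
- **`canopyflow.correction`** — the dynamic windward-area model `s*(v*)` for
  the outer 0–0.3 m layer (leaves fold together at high airflow until a
  saturation velocity) and the piecewise two-layer velocity profile.
- **`canopyflow.validation`** — per-point error `v_w = |v₂ − v₁|` and accuracy
  `I = (1 − v_w/v₁)·100 %`, profile-level reports, R², mean relative error.
- **`canopyflow.imaging`** — windward leaf area from white-background canopy
  projection photographs (Otsu threshold inside the marked circular ROI).
- **`canopyflow.synthetic`** — seeded generators for drag campaigns, noisy
  anemometer profiles, and synthetic projection images with known coverage.
- **`canopyflow.cli`** — a `canopyflow` command with `fit-k`, `predict`,
  `validate`, `windward-area`, and `simulate` subcommands.

## CLI usage

```bash
# estimate k for every row of a drag campaign (CSV columns:
# leaf_area_density, v_star, force_N, s_m2, R_m, D_m, D_prime_m)
canopyflow fit-k campaign.csv --out model.json

# predict an in-canopy velocity profile from a fitted model
canopyflow predict model.json --v-star 8 --density 4.15 \
    --depths 0.15,0.3,0.45,0.6,0.75,0.9 --out profile.csv

# score a theoretical profile against measurements
canopyflow validate profile.csv measured.csv

# windward leaf area from a projection photo (ROI: row,col,radius px)
canopyflow windward-area canopy.png --roi 150,150,120 --scale 0.00133

# generate a synthetic campaign from a YAML spec
canopyflow simulate spec.yaml --out-csv campaign.csv --out-truth truth.json
```

Defaults (overridable via `--config config.yaml`): air density ρ = 1.29 kg/m³,
drag coefficient C_d = 1.0, jet radius R = 0.16 m, canopy depth D = 0.9 m,
section thickness D′ = 0.3 m.

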