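# aeromarine

Air–sea exchange and long-range transport of airborne microbes over the
low-latitude ocean.

The atmosphere over the open ocean carries a substantial load of prokaryotes
and unicellular eukaryotes (mostly fungal spores). Two opposing fluxes set
that load: sea-spray aerosolisation injects cells from the surface ocean,
and dry deposition returns them. `aeromarine` implements the full analysis
chain that turns station-level observations — wind, temperature, humidity,
pressure, airborne abundances (cells m⁻³) and surface-water abundances
(cells ml⁻¹) — into:

* **exchange fluxes**: dry deposition `F_d = v_d·C_air` with a two-layer
  (Williams-type) deposition velocity over smooth and whitecap-broken sea
  surface, and spray emission `F_s = V̇_T·C_water` with the Gong (2003)
  source function integrated over r80 ∈ [0.2, 10] µm;
* the **steady-state oceanic contribution** `C_eq = V̇_T·C_water / v_d`, the
  airborne abundance the local ocean alone can sustain, and the signed
  **terrestrial excess** `C_air − C_eq` attributed to advection from land;
* **distance-decay statistics**: the excess and abundance decay as
  `y = a·e^(−bD)` with distance to the nearest land mass `D` (km), fitted by
  nonlinear least squares with AIC model selection and 8-bin summaries;
* **boundary-layer transport**: ABL heights from potential-temperature
  profiles (θ ≥ θ_min + 2 K), column loads `C_air·H`, residence half-times
  `t₅₀ = H·ln2/v_d` and maximum trajectory excursions within `t₅₀`;
* **global upscaling**: spherical grids with exact cell areas, coastline
  distance fields, area-integrated loads and yearly gross/net flux and
  carbon budgets between 40° S and 40° N.

A seeded synthetic-cruise generator (`aeromarine.synthetic_data`) emulates
the statistical structure of a circumnavigation — equilibrium baseline plus
exponentially decaying terrestrial excess with multiplicative lognormal
noise, idealised coastlines with optional island chains — so every stage
runs and is tested at desk scale without any external data.

## Worked example

```python
import numpy as np
from aeromarine import (CruiseConfig, simulate_cruise, station_fluxes,
                        fit_exponential_decay, fraction_remaining,
                        residence_half_time, PROKARYOTE)

records, coast = simulate_cruise(CruiseConfig(seed=7))
D = np.array([r.distance_to_land for r in records])
excess = np.array([station_fluxes(r.c_air_prok, r.c_water_prok,
                                  r.meteo, PROKARYOTE).excess
                   for r in records])
fit = fit_exponential_decay(D, excess, weights="relative")
print(f"decay rate b = {fit.rate:.5f} /km")
print(f"fraction surviving 1000 km = "
      f"{100 * fraction_remaining(fit, 1000.0):.1f} %")
print(f"t50 at v_d = 3.86e-4 m/s, H = 817 m: "
      f"{residence_half_time(3.86e-4, 817.0) / 86400:.1f} d")
```

prints

```
decay rate b = 0.00361 /km
fraction surviving 1000 km = 2.7 %
t50 at v_d = 3.86e-4 m/s, H = 817 m: 17.0 d
```

The generator planted a coastal excess decaying at 0.0037 km⁻¹; the fit
recovers it from 120 noisy stations, and evaluating the normalised decay at
1000 km shows that only a few percent of the terrestrial excess survives
that far offshore. At the observed median deposition velocity, half of the airborne
prokaryote load stays aloft for ~17 days — long enough for transoceanic
transport.

The same pipeline is available from a shell:

```bash
aeromarine simulate --seed 7 --out stations.csv        # + stations.geojson
aeromarine fluxes   --stations stations.csv --out fluxes.csv
aeromarine fit      --stations stations.csv --target excess --out fit.json
aeromarine residence --fluxes fluxes.csv --out residence.csv
aeromarine upscale  --fit fit.json --coastline stations.geojson \
                    --resolution 1 --lon-domain -20 40 --out global.json
```

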