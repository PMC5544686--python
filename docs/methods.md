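# Methods

This note documents the models behind `aeromarine`, the parameter defaults
and why they were chosen, the numerical choices, and what the synthetic-data
tests do and do not demonstrate about real observations.

## Units and conventions

Internally everything is SI (m, s, K, Pa, cells m⁻³, g), with two
field-standard exceptions carried through the data contracts: horizontal
geographic distances are in km (so decay rates are km⁻¹) and precipitation
rate in mm h⁻¹. Unit conversion happens only at the I/O boundary
(`core_io`), driven by a dialect mapping (°C/K, hPa/Pa, cells ml⁻¹ /
cells m⁻³). Longitudes are normalised to [−180, 180). Fluxes are stored in
s⁻¹; reporting layers convert to d⁻¹ or y⁻¹ (365.25 d). Net flux is
*deposition positive*; map-style products that plot deposition as negative
should negate at the writer.

## Dry deposition velocity

Deposition of a particle of diameter d and density ρ to the sea surface is
modelled with a two-layer resistance scheme. Gravitational settling

  v_g = ρ d² g C_c / (18 μ(T))

uses Sutherland's law for the air viscosity μ(T) and the Cunningham slip
correction C_c with coefficients 1.257/0.4/1.1 and mean free path
λ(T, P) = 0.0665 µm · (T/298.15 K)(1013.25 hPa/P). Transfer through the
constant-flux layer is k_a = C_D u₁₀ with a neutral drag coefficient
C_D = 1.3×10⁻³ (friction velocity u* = √C_D·u₁₀). Surface uptake acts in
parallel over two surface states:

* smooth surface: k_ss = (u*²/u₁₀)(Sc^(−1/2) + 10^(−3/St)) — Brownian
  diffusion plus inertial impaction, the deposition-layer form of the
  Slinn & Slinn overwater model;
* broken surface (whitecaps): k_bs = u*, i.e. efficient uptake by the
  bursting-bubble surface, weighted by the whitecap fraction
  α = 1.7×10⁻⁶ u₁₀^3.75 (capped at 1).

Each pathway combines layers in series with settling acting in both:
v(k_a, k_s) = (k_a+v_g)(k_s+v_g)/(k_a+k_s+v_g), and
v_d = (1−α)·v(k_a, k_ss) + α·v(k_a, k_bs). This construction guarantees
v_d ≥ v_g, v_d → v_g as u₁₀ → 0, and monotone growth with wind. The
specific constant set is not uniquely fixed by the literature chain this
model descends from; all constants live in `DepositionParams` and are
config-overridable. With these defaults the standard-condition equilibrium
range (below) reproduces the observed 3×10³–1.3×10⁴ cells m⁻³ envelope,
and the submicron v_d is whitecap-dominated at fresh winds — prokaryote
v_d spans ~3×10⁻⁵ (calm) to ~5×10⁻⁴ m s⁻¹ (12–13 m s⁻¹).

Microbial particle classes default to 0.5 µm (prokaryotes) and 5 µm
(eukaryotes/fungal spores) at 1.1 g cm⁻³, with carbon contents 12.4 fg and
13 pg C cell⁻¹. The deposition diameter is the measured mean diameter; no
hygroscopic growth step is applied (RH enters only through the
parameterisation's own terms).

## Sea-spray source and emission

The Gong (2003) source function gives the number flux density per r80
(radius at 80 % RH, µm):

  dF/dr = 1.373 u₁₀^3.41 r^(−A) (1 + 0.057 r^3.45) · 10^(1.607 e^(−B²)),
  A = 4.7(1+Θr)^(−0.017 r^(−1.44)), B = (0.433 − log₁₀ r)/0.433, Θ = 30.

The spray volume velocity V̇_T integrates dF/dr·(4/3)πr³ over
r80 ∈ [0.2, 10] µm (radii in metres inside the volume factor). Because u₁₀
factors out, V̇_T is computed once at unit wind by adaptive quadrature in
log-radius (relative tolerance 10⁻¹⁰, cached per parameter set) and scaled
by u₁₀^3.41; tests verify agreement with a 10⁶-step midpoint-Riemann
evaluation to better than 0.1 %. Emission of cells is F_s = V̇_T·C_water,
assuming non-preferential aerosolisation — bubble scavenging concentrates
microbes at the surface, so marine contributions may be underestimated.

## Steady state, excess, wet deposition, carbon

Setting F_d = F_s gives the equilibrium airborne abundance
C_eq = V̇_T·C_water/v_d, the "oceanic contribution". The terrestrial excess
C_air − C_eq is kept signed: stations can sit below equilibrium, and bin
means average the signed values. Sweeping standard conditions (25 °C, 80 %
RH, 1025 hPa), u₁₀ ∈ [6, 12] m s⁻¹ and C_water ∈ [0.5, 1.5]×10⁶ cells ml⁻¹
spans C_eq ≈ 3.9×10³–1.6×10⁴ cells m⁻³.

Wet deposition uses a generic scavenging-ratio model F_wet = W·C_air·p
(p converted from mm h⁻¹ to m s⁻¹), with W = 500 by default — the mid-range
of literature values for micron aerosol; it is a stand-in for episodic rain
events and is config-overridable. Carbon conversion is a straight product
of cell count and per-cell carbon.

## Boundary layer and residence

ABL height is the lowest height at which the potential temperature reaches
its profile minimum plus 2 K, linearly interpolated between levels; a
profile that never crosses the threshold is an error rather than a guess.
When no profile or reanalysis height is available, the climatological means
817 m (ocean) and 564 m (land) are used. Column load is C_air·H for a
well-mixed layer. Removal by deposition alone drains the column as
R(t) = e^(−v_d t/H), so t₅₀ = H ln2/v_d; with H = 817 m this gives 17 d at
v_d = 3.86×10⁻⁴ m s⁻¹ and 3.5 d at 1.87×10⁻³ m s⁻¹. Transport range is
the maximum haversine distance from the trajectory origin over all points
within t₅₀ (position at exactly t₅₀ interpolated); a trajectory that ends
early returns its full-path maximum flagged `truncated`. Rain shortens real
residence times; that effect is noted, not modelled.

## Distance-decay fitting

Responses (abundance, excess, load) are fitted as y = a·e^(−bD) by
nonlinear least squares, seeded by a log-linear regression on the positive
responses (non-positive values are excluded from the seed only). R² is
1 − RSS/TSS on the untransformed response and AIC = n ln(RSS/n) + 2k with
k = 3 (a, b, error variance); the linear alternative has the same k, and
AIC ties break toward fewer parameters. Binning is equal-count (quantile)
over 8 bins by default, with equal-width available; SEM is undefined for
single-member bins and reported as missing. Ordinary (unweighted) least
squares is the default; `weights="relative"` applies iteratively
reweighted least squares with σ ∝ fitted value, the appropriate weighting
when the noise is multiplicative, and is what the parameter-recovery
experiment uses. Whether the observed-figure fits were SEM-weighted is not
documented; fitting on bin means yields the high R² values characteristic of the
observed decay relationships and is the mode used for figure-parity
reports.

## Gridding and upscaling

Grids are cell-edge registered with half-open cells and exact spherical
areas R²Δλ(sin φ₂ − sin φ₁), R = 6371 km; a global grid closes 4πR² to
10⁻⁹ relative by construction (telescoping sine sums). Land masking tests
cell centers against the coastline polygons; distance to land is the
minimum haversine distance to the coastline densified to ≤ 10 km vertex
spacing (error bounded well below the grid scale), computed through a
KD-tree on 3-D unit vectors. Global load sums a·e^(−bD)·A over ocean
cells; an abundance fit is converted to a load fit by multiplying the
amplitude by the ABL height (per-cell heights when available, else the
817 m ocean mean). Flux upscaling evaluates per-cell v_d and V̇_T from
gridded meteorology, integrates over area and a 365.25-d year, and brackets
emission with the observed min/max surface-water abundances; net = gross
deposition − maximum gross emission. Field regridding is bilinear with
constant extrapolation at the domain edge.

Reproducing the observed-world global totals (≈2×10²¹ cells per domain)
requires the real bathymetry-derived distance field, reanalysis meteorology and the
per-station supplementary tables; the package instead verifies its
integration machinery against closed forms (half-plane ocean vs strip
integral a/b per metre of coast, agreement within 2 % at 1° resolution)
and runs the full chain on synthetic worlds.

## Synthetic cruise generator

`simulate_cruise` draws stations on the ocean side of an idealised
coastline (rectangular continents, optional island chains for
stepping-stone geometries). Station distances follow a mixture — 60 %
"coastal leg" uniform in 10–1000 km, 40 % "open ocean" uniform in
1000–4000 km — chosen to resemble a circumnavigation that alternates
island-rich and remote legs and to populate all 8 distance bins.
Meteorology is uniform within a low-latitude cruise envelope
(u₁₀ 3–12 m s⁻¹, T 290–303 K, RH 60–90 %, P 1000–1025 hPa), surface-water
abundance uniform in 0.5–1.5×10⁶ cells ml⁻¹. Airborne abundance is

  C_air = C_eq(meteo, C_water) + a·e^(−bD)·ε,  ε lognormal, E[ε] = 1,

with defaults a = 25454 cells m⁻³, b = 0.0037 km⁻¹ (prokaryotes; 19881 and
0.00085 for eukaryotes) and CV 0.5. The noise multiplies the terrestrial
excess: it represents the variability of the advected load (air-mass
history, source strength), while the equilibrium term is by construction
the deterministic steady state of the same measured meteorology that the
pipeline later subtracts. `noise_on="total"` instead applies the factor to
the whole abundance (measurement-noise reading); identifiability of b is
then markedly poorer because far-field excess estimates inherit
equilibrium-scale noise. All draws flow from one `numpy` Generator, so a
seed fixes the cruise byte for byte.

What the generator does *not* emulate: spatial autocorrelation along the
track, seasonal/regional structure, correlated meteorology, dust events,
wet scavenging, community composition, or deviations of the real
excess–distance relationship from a single exponential. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not the fidelity
of those assumptions to the real atmosphere.

## Problem sizes and determinism

Default experiment sizes — 120 stations per cruise, 200 replicates in the
recovery experiment, 1° grids over a 65°-wide basin — keep any single
analysis under a few seconds while leaving estimator noise well below the
tolerances asserted in the tests. Hypothesis-based property tests run
derandomised; every stochastic test and script takes an explicit seed.

## Known limitations

* The deposition-model constant set follows a literature chain whose exact
  coefficients are not uniquely documented; other defensible choices shift
  v_d for submicron particles by factors of a few. They are exposed in
  configuration rather than hard-coded.
* The wet-deposition scavenging model and its W = 500 default are generic.
* Distance to land is point-to-sampled-coastline; for coastlines densified
  at 10 km the error is ≤ 5 km, negligible at basin scale but visible for
  stations hugging the shore.
* `global_fluxes` loops over cells with scalar microphysics calls; at 2.5°
  this is instant, but a 0.25° global grid would warrant vectorisation.
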