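"""Synthetic cruise worlds: desk-scale stand-ins for the field campaign.

The generator emulates the statistical structure the analysis assumes: the
airborne abundance at a station is the deterministic ocean-atmosphere
equilibrium implied by its own meteorology and surface-water abundance, plus
a terrestrial excess decaying exponentially with distance to an idealised
coastline.  Multiplicative lognormal noise (mean 1, configurable CV)
represents the variability of the advected terrestrial load; by default it
multiplies the excess component, the equilibrium baseline being by
construction the deterministic steady state of the same measured meteorology
the pipeline later subtracts (``noise_on="total"`` applies it to the whole
abundance instead).  All randomness flows from a single seeded generator, so
one seed reproduces the cruise byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (EUKARYOTE, PROKARYOTE, MeteoState, StationRecord,
                      ThetaProfile, TrajectoryPath)
from .exchange import equilibrium_air_concentration
from .geo import EARTH_RADIUS_KM, coastline_points, min_distance_to_points_km

__all__ = ["CruiseConfig", "make_coastline", "simulate_cruise",
           "make_theta_profiles", "make_trajectories", "make_meteo_fields"]


#: Default synthetic world: one meridional continent west of the study ocean.
DEFAULT_COASTLINE_SPEC = {
    "continents": [
        {"lon_min": -20.0, "lon_max": 0.0, "lat_min": -65.0, "lat_max": 65.0},
    ],
    "island_chains": [],
}


@dataclass
class CruiseConfig:
    """Study conditions of a synthetic circumnavigation.

    Excess amplitudes/rates default to the observed cruise decay
    coefficients (prokaryote excess 25454 cells m^-3 at the coast decaying
    at 0.0037 km^-1; eukaryote 19881 cells m^-3 at 0.00085 km^-1); water
    abundances span the typical open-ocean range 0.5-1.5 x 1e6 cells ml^-1,
    and meteorology the envelope of a low-latitude cruise.
    """

    n_stations: int = 120
    seed: int = 0
    excess_amplitude: float = 25454.0      # cells m^-3 (prokaryotes)
    excess_rate: float = 0.0037            # km^-1
    euk_excess_amplitude: float = 19881.0  # cells m^-3
    euk_excess_rate: float = 0.00085       # km^-1
    noise_cv: float = 0.5
    noise_on: str = "excess"               # "excess" | "total"
    c_water_range_ml: tuple = (0.5e6, 1.5e6)   # cells ml^-1
    u10_range: tuple = (3.0, 12.0)         # m s^-1
    T_range: tuple = (290.0, 303.0)        # K
    RH_range: tuple = (60.0, 90.0)         # %
    P_range: tuple = (1.0e5, 1.025e5)      # Pa
    lat_range: tuple = (-35.0, 35.0)
    # distance mixture: coastal/island legs vs open-ocean legs
    near_fraction: float = 0.6
    near_distance_km: tuple = (10.0, 1000.0)
    far_distance_km: tuple = (1000.0, 4000.0)
    coastline_spec: dict = field(default_factory=lambda: dict(DEFAULT_COASTLINE_SPEC))

    def __post_init__(self) -> None:
        if self.excess_amplitude < 0 or self.noise_cv < 0:
            raise ValueError("amplitude and noise_cv must be >= 0")
        for rng in (self.c_water_range_ml, self.u10_range, self.T_range,
                    self.RH_range, self.P_range, self.near_distance_km,
                    self.far_distance_km):
            if rng[0] > rng[1]:
                raise ValueError(f"range out of order: {rng}")
        if self.noise_on not in ("excess", "total"):
            raise ValueError("noise_on must be 'excess' or 'total'")


def make_coastline(spec: dict | None = None):
    """Build an idealised coastline (shapely geometry) from a spec of
    rectangular continents and island chains.

    Island chains are rows of small square islands along a parallel, spaced
    ``spacing_km`` apart, the geometry behind the stepping-stone effect.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    spec = spec or DEFAULT_COASTLINE_SPEC
    geoms = []
    for c in spec.get("continents", []):
        geoms.append(box(c["lon_min"], c["lat_min"],
                         c["lon_max"], c["lat_max"]))
    for ch in spec.get("island_chains", []):
        lat = ch["lat"]
        spacing_deg = (ch["spacing_km"]
                       / (EARTH_RADIUS_KM * math.pi / 180.0)
                       / max(math.cos(math.radians(lat)), 1e-6))
        half = ch.get("island_radius_km", 15.0) / (EARTH_RADIUS_KM * math.pi / 180.0)
        lon = ch["lon_start"]
        while lon <= ch["lon_end"]:
            geoms.append(box(lon - half, lat - half, lon + half, lat + half))
            lon += spacing_deg
    if not geoms:
        raise ValueError("coastline spec has no land features")
    return unary_union(geoms)


def _lognormal_factor(rng, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of
    variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return rng.lognormal(-sigma ** 2 / 2.0, sigma, size)


def simulate_cruise(config: CruiseConfig | None = None):
    """Generate stations for one synthetic cruise.

    Returns ``(records, coastline)``.  Station positions are placed due east
    of the synthetic continent so their coastline distances follow a mixture
    emphasising both coastal and open-ocean legs; the recorded
    ``distance_to_land`` is recomputed against the actual coastline
    geometry, exactly as the real pipeline would.
    """
    cfg = config or CruiseConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_stations
    coast = make_coastline(cfg.coastline_spec)
    coast_pts = coastline_points(coast, 10.0)
    coast_lon = max(c["lon_max"] for c in cfg.coastline_spec["continents"])

    lat = rng.uniform(*cfg.lat_range, n)
    near = rng.random(n) < cfg.near_fraction
    target = np.where(near, rng.uniform(*cfg.near_distance_km, n),
                      rng.uniform(*cfg.far_distance_km, n))
    # longitude offset giving the target cross-track distance to the coast
    arg = np.clip(np.sin(target / EARTH_RADIUS_KM)
                  / np.cos(np.radians(lat)), -1.0, 1.0)
    lon = coast_lon + np.degrees(np.arcsin(arg))
    dist = min_distance_to_points_km(lat, lon, coast_pts)

    u10 = rng.uniform(*cfg.u10_range, n)
    T = rng.uniform(*cfg.T_range, n)
    RH = rng.uniform(*cfg.RH_range, n)
    P = rng.uniform(*cfg.P_range, n)
    c_water = rng.uniform(*cfg.c_water_range_ml, n) * 1.0e6  # -> cells m^-3
    noise_p = _lognormal_factor(rng, cfg.noise_cv, n)
    noise_e = _lognormal_factor(rng, cfg.noise_cv, n)

    records = []
    t0 = pd.Timestamp("2010-12-15")
    for i in range(n):
        meteo = MeteoState(u10=float(u10[i]), T=float(T[i]), RH=float(RH[i]),
                           P=float(P[i]))
        ceq_p = equilibrium_air_concentration(float(c_water[i]), meteo,
                                              PROKARYOTE)
        ceq_e = equilibrium_air_concentration(float(c_water[i]), meteo,
                                              EUKARYOTE)
        exc_p = cfg.excess_amplitude * math.exp(-cfg.excess_rate * dist[i])
        exc_e = cfg.euk_excess_amplitude * math.exp(-cfg.euk_excess_rate
                                                    * dist[i])
        if cfg.noise_on == "excess":
            c_air_p = ceq_p + exc_p * noise_p[i]
            c_air_e = ceq_e + exc_e * noise_e[i]
        else:
            c_air_p = (ceq_p + exc_p) * noise_p[i]
            c_air_e = (ceq_e + exc_e) * noise_e[i]
        records.append(StationRecord(
            id=f"S{i + 1:03d}", lat=float(lat[i]), lon=float(lon[i]),
            time=t0 + pd.Timedelta(hours=18 * i),
            distance_to_land=float(dist[i]), meteo=meteo,
            c_air_prok=float(c_air_p), c_air_euk=float(c_air_e),
            c_water_prok=float(c_water[i])))
    return records, coast


def make_theta_profiles(n: int, seed: int = 0, dz: float = 50.0,
                        z_top: float = 4000.0):
    """Linear potential-temperature profiles with analytically known ABL
    heights.  Returns a list of ``(ThetaProfile, expected_height_m)``; the
    2-K threshold of a profile with lapse rate s is crossed at z = 2 / s.
    """
    rng = np.random.default_rng(seed)
    out = []
    z = np.arange(0.0, z_top + dz, dz)
    for _ in range(n):
        theta0 = rng.uniform(295.0, 305.0)
        slope = rng.uniform(0.005, 0.02)  # K m^-1
        prof = ThetaProfile(tuple(zip(z, theta0 + slope * z)))
        out.append((prof, 2.0 / slope))
    return out


def make_trajectories(n: int, seed: int = 0,
                      speed_range=(2.0, 15.0), duration_days: float = 25.0,
                      step_h: float = 1.0):
    """Constant-speed due-east trajectories along the equator, whose maximum
    excursion from the origin after time t is exactly speed x t (until half
    the globe is covered).  Returns list of (TrajectoryPath, speed m/s)."""
    rng = np.random.default_rng(seed)
    out = []
    times = np.arange(0.0, duration_days * 86400.0 + 1.0, step_h * 3600.0)
    for _ in range(n):
        speed = rng.uniform(*speed_range)
        lon0 = rng.uniform(-180.0, 120.0)
        lon = lon0 + np.degrees(times * speed / (EARTH_RADIUS_KM * 1000.0))
        pts = tuple((float(t), 0.0, float(lo), 10.0)
                    for t, lo in zip(times, lon))
        out.append((TrajectoryPath(pts), speed))
    return out


def make_meteo_fields(grid, seed: int = 0,
                      u10_range=(3.0, 12.0), T_range=(290.0, 303.0),
                      RH_range=(60.0, 90.0), P_range=(1.0e5, 1.025e5)):
    """Smooth random meteorology fields on a GeoGrid, bounded by the cruise
    envelope.  Each field is a low-order random harmonic surface mapped into
    its range, deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    LAT, LON = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")

    def surface(lo, hi):
        ph = rng.uniform(0, 2 * np.pi, 4)
        k = rng.integers(1, 4, 2)
        s = (np.sin(np.radians(LAT) * k[0] + ph[0])
             + np.cos(np.radians(LON) * k[1] + ph[1])
             + 0.5 * np.sin(np.radians(LAT + LON) + ph[2]))
        s = (s - s.min()) / max(s.max() - s.min(), 1e-12)
        return lo + (hi - lo) * s

    return {"u10": surface(*u10_range), "T": surface(*T_range),
            "RH": surface(*RH_range), "P": surface(*P_range)}
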