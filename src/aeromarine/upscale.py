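"""Global (40 S - 40 N) integration of microbial loads and exchange fluxes.

A regular lat/lon grid (cell-edge registered, half-open cells) carries a land
mask, a distance-to-land field and exact spherical cell areas
A = R^2 dlon (sin lat2 - sin lat1).  The fitted load-distance decay is
evaluated per ocean cell, multiplied by its area and summed; gridded
abundance and meteorology fields give gross deposition and (from the
observed min/max surface-water abundances) gross emission, hence net
deposition and its carbon equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MeteoState, ParticleClass
from .exchange import SECONDS_PER_YEAR, cells_to_carbon
from .fitstats import DecayFit
from .geo import EARTH_RADIUS_KM, coastline_points, min_distance_to_points_km
from .microphysics import (DepositionParams, SpraySourceParams,
                           deposition_velocity, spray_volume_velocity)

__all__ = ["GeoGrid", "GlobalEstimate", "build_grid", "distance_to_land",
           "global_load", "global_fluxes", "interpolate_field"]

EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0


@dataclass
class GeoGrid:
    """Regular lat/lon grid with land mask, distances and cell areas."""

    lat_edges: np.ndarray           # degrees, ascending
    lon_edges: np.ndarray           # degrees, ascending
    land_mask: np.ndarray           # (nlat, nlon) bool, True = land
    distance_to_land: np.ndarray | None  # km, NaN over land
    cell_area: np.ndarray           # (nlat, nlon) m^2

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def ocean(self) -> np.ndarray:
        return ~self.land_mask


@dataclass
class GlobalEstimate:
    """Domain-integrated loads (cells) and yearly fluxes (cells y^-1)."""

    total_load: dict = field(default_factory=dict)
    gross_emission_min: dict = field(default_factory=dict)
    gross_emission_max: dict = field(default_factory=dict)
    gross_deposition: dict = field(default_factory=dict)
    net_deposition: dict = field(default_factory=dict)       # dep - max emission
    carbon_net_tg: dict = field(default_factory=dict)        # Tg C y^-1


def cell_areas(lat_edges: np.ndarray, lon_edges: np.ndarray) -> np.ndarray:
    """Exact spherical areas (m^2) of the cells of an edge-registered grid."""
    dlon = np.radians(np.diff(lon_edges))
    band = (np.sin(np.radians(lat_edges[1:]))
            - np.sin(np.radians(lat_edges[:-1])))
    return EARTH_RADIUS_M ** 2 * np.outer(band, dlon)


def build_grid(resolution: float, lat_bounds=(-40.0, 40.0),
               lon_bounds=(-180.0, 180.0), coastline=None,
               coast_spacing_km: float = 10.0) -> GeoGrid:
    """Build a GeoGrid at ``resolution`` degrees over the given domain.

    The resolution must divide both domain extents evenly.  When a coastline
    geometry is given, cell centers inside land polygons are masked and the
    distance-to-land field is computed for ocean cells from the coastline
    densified to ``coast_spacing_km`` vertex spacing.
    """
    lat0, lat1 = lat_bounds
    lon0, lon1 = lon_bounds
    if lat1 <= lat0 or lon1 <= lon0:
        raise ValueError("empty domain")
    nlat = (lat1 - lat0) / resolution
    nlon = (lon1 - lon0) / resolution
    if abs(nlat - round(nlat)) > 1e-9 or abs(nlon - round(nlon)) > 1e-9:
        raise ValueError("resolution must divide the domain evenly")
    lat_edges = lat0 + resolution * np.arange(round(nlat) + 1)
    lon_edges = lon0 + resolution * np.arange(round(nlon) + 1)
    area = cell_areas(lat_edges, lon_edges)

    nla, nlo = area.shape
    mask = np.zeros((nla, nlo), dtype=bool)
    dist = None
    if coastline is not None:
        latc = 0.5 * (lat_edges[:-1] + lat_edges[1:])
        lonc = 0.5 * (lon_edges[:-1] + lon_edges[1:])
        LON, LAT = np.meshgrid(lonc, latc)
        mask = _land_mask(coastline, LAT, LON)
        pts = coastline_points(coastline, coast_spacing_km)
        dist = np.full((nla, nlo), np.nan)
        ocean = ~mask
        dist[ocean] = min_distance_to_points_km(LAT[ocean], LON[ocean], pts)
    return GeoGrid(lat_edges, lon_edges, mask, dist, area)


def _land_mask(coastline, LAT, LON) -> np.ndarray:
    from shapely import contains_xy
    from shapely.geometry import MultiPolygon, Polygon
    from shapely.ops import unary_union

    polys = []

    def collect(g):
        if isinstance(g, (Polygon, MultiPolygon)):
            polys.append(g)
        elif hasattr(g, "geoms"):
            for sub in g.geoms:
                collect(sub)

    collect(coastline)
    if not polys:
        return np.zeros(LAT.shape, dtype=bool)
    land = unary_union(polys)
    return contains_xy(land, LON.ravel(), LAT.ravel()).reshape(LAT.shape)


def distance_to_land(lat, lon, coastline, spacing_km: float = 10.0):
    """Minimum haversine distance (km) from points to the coastline,
    densified to at most ``spacing_km`` between samples."""
    pts = coastline_points(coastline, spacing_km)
    return min_distance_to_points_km(lat, lon, pts)


def global_load(grid: GeoGrid, load_fit: DecayFit) -> float:
    """Total cells over the ocean cells of the grid for an exponential
    load-distance fit (amplitude in cells m^-2)."""
    if grid.distance_to_land is None:
        raise ValueError("grid lacks a distance-to-land field")
    if load_fit.fit_target != "load":
        raise ValueError("global_load expects a column-load fit "
                         "(fit_target='load', cells m^-2)")
    ocean = grid.ocean
    load = load_fit.predict(grid.distance_to_land[ocean])
    return float((load * grid.cell_area[ocean]).sum())


def abundance_to_load_fit(fit: DecayFit, abl_height_m: float) -> DecayFit:
    """Convert an abundance fit (cells m^-3) to a column-load fit
    (cells m^-2) for a well-mixed layer of the given height."""
    return DecayFit(amplitude=fit.amplitude * abl_height_m, rate=fit.rate,
                    r_squared=fit.r_squared, aic=fit.aic, n=fit.n,
                    fit_target="load", binned=fit.binned)


def global_fluxes(grid: GeoGrid, abundance_field: np.ndarray,
                  meteo_fields: dict, c_water_range: tuple[float, float],
                  particle: ParticleClass,
                  dep_params: DepositionParams | None = None,
                  spray_params: SpraySourceParams | None = None
                  ) -> GlobalEstimate:
    """Integrate gross deposition and emission over the ocean for a year.

    abundance_field : cells m^-3 per cell, aligned with the grid.
    meteo_fields : dict of per-cell arrays ``u10``, ``T``, ``RH``, ``P``.
    c_water_range : (min, max) surface-water abundance, cells m^-3, driving
        the emission-flux range.
    """
    shp = grid.cell_area.shape
    if abundance_field.shape != shp:
        raise ValueError(f"abundance field shape {abundance_field.shape} "
                         f"does not match grid {shp}")
    for k in ("u10", "T", "RH", "P"):
        if meteo_fields[k].shape != shp:
            raise ValueError(f"meteo field {k!r} misaligned with grid")

    ocean = grid.ocean
    area = grid.cell_area
    dep = emi = 0.0
    for i, j in zip(*np.nonzero(ocean)):
        meteo = MeteoState(u10=float(meteo_fields["u10"][i, j]),
                           T=float(meteo_fields["T"][i, j]),
                           RH=float(meteo_fields["RH"][i, j]),
                           P=float(meteo_fields["P"][i, j]))
        v_d = deposition_velocity(particle, meteo, dep_params)
        v_s = spray_volume_velocity(meteo, spray_params)
        dep += v_d * abundance_field[i, j] * area[i, j]
        emi += v_s * area[i, j]
    dep_y = dep * SECONDS_PER_YEAR
    emi_min = emi * c_water_range[0] * SECONDS_PER_YEAR
    emi_max = emi * c_water_range[1] * SECONDS_PER_YEAR
    net = dep_y - emi_max
    out = GlobalEstimate()
    name = particle.name
    out.gross_deposition[name] = dep_y
    out.gross_emission_min[name] = emi_min
    out.gross_emission_max[name] = emi_max
    out.net_deposition[name] = net
    out.carbon_net_tg[name] = cells_to_carbon(max(net, 0.0), particle,
                                              teragrams=True)
    return out


def interpolate_field(field: np.ndarray, src: GeoGrid, dst: GeoGrid
                      ) -> np.ndarray:
    """Bilinear interpolation of a cell-center field from one grid to
    another; target centers outside the source centers are clamped to the
    edge (constant extrapolation).  Constant fields map to constant fields.
    """
    from scipy.interpolate import RegularGridInterpolator

    slat, slon = src.lat_centers, src.lon_centers
    dlat, dlon = dst.lat_centers, dst.lon_centers
    if (dlat.min() > slat.max() or dlat.max() < slat.min()
            or dlon.min() > slon.max() or dlon.max() < slon.min()):
        raise ValueError("grids do not overlap")
    interp = RegularGridInterpolator((slat, slon), field, method="linear",
                                     bounds_error=False, fill_value=None)
    LA, LO = np.meshgrid(np.clip(dlat, slat[0], slat[-1]),
                         np.clip(dlon, slon[0], slon[-1]), indexing="ij")
    return interp(np.stack([LA.ravel(), LO.ravel()], axis=1)).reshape(LA.shape)
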