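"""Spherical-earth geometry helpers (haversine distances, coastline sampling).

All distances use a spherical Earth of radius 6371.0 km, consistent with the
precision of every quantity in the pipeline.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "coastline_points",
           "min_distance_to_points_km"]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points given in degrees."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((p2 - p1) / 2.0) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _unit_vectors(lat_deg, lon_deg) -> np.ndarray:
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def coastline_points(coastline, spacing_km: float = 10.0) -> np.ndarray:
    """Sample a shapely coastline geometry to (lat, lon) vertices with at
    most ``spacing_km`` between consecutive samples along each boundary.

    Works on polygons (their exterior/interior rings), lines and points.
    Geometry coordinates are (lon, lat) degrees, the GeoJSON convention.
    """
    from shapely.geometry import (GeometryCollection, LinearRing, LineString,
                                  MultiLineString, MultiPoint, MultiPolygon,
                                  Point, Polygon)

    # one degree of latitude in km; used to translate the spacing to degrees
    deg = spacing_km / (EARTH_RADIUS_KM * np.pi / 180.0)
    out: list[np.ndarray] = []

    def add_line(line) -> None:
        dens = line.segmentize(deg)
        xy = np.asarray(dens.coords)
        out.append(xy[:, [1, 0]])  # -> (lat, lon)

    def walk(geom) -> None:
        if isinstance(geom, (Polygon,)):
            add_line(geom.exterior)
            for ring in geom.interiors:
                add_line(ring)
        elif isinstance(geom, (LineString, LinearRing)):
            add_line(geom)
        elif isinstance(geom, Point):
            out.append(np.array([[geom.y, geom.x]]))
        elif isinstance(geom, (MultiPolygon, MultiLineString, MultiPoint,
                               GeometryCollection)):
            for g in geom.geoms:
                walk(g)
        else:
            raise TypeError(f"unsupported geometry: {geom.geom_type}")

    walk(coastline)
    if not out:
        raise ValueError("coastline geometry is empty")
    return np.vstack(out)


def min_distance_to_points_km(lat, lon, coast_latlon: np.ndarray) -> np.ndarray:
    """Minimum haversine distance (km) from query points to a sampled point
    set, via a KD-tree on 3-D unit vectors (chord metric, converted to arc)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(_unit_vectors(coast_latlon[:, 0], coast_latlon[:, 1]))
    q = _unit_vectors(lat, lon)
    chord, _ = tree.query(np.atleast_2d(q))
    arc = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    d = EARTH_RADIUS_KM * arc
    return float(d[0]) if np.isscalar(lat) else d.reshape(np.shape(lat))
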