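"""Domain types and file I/O for the air-sea microbial exchange pipeline.

Internal unit system is SI (m, s, K, Pa, cells m^-3, g) with two field-standard
exceptions that are part of the data contracts: horizontal geographic distances
are carried in km (distance to land, decay-rate units km^-1) and precipitation
rate in mm h^-1, the unit rain gauges report.  All conversions happen at the
I/O boundary, controlled by a small dialect mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("aeromarine")

__all__ = [
    "ParticleClass",
    "MeteoState",
    "StationRecord",
    "TrajectoryPath",
    "ThetaProfile",
    "PROKARYOTE",
    "EUKARYOTE",
    "read_stations",
    "write_stations",
    "read_trajectory",
    "read_coastline",
    "write_coastline",
    "load_config",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ParticleClass:
    """A microbial class treated as a spherical aerosol particle.

    Parameters
    ----------
    name : str
        Label, e.g. ``"prokaryote"``.
    diameter : float
        Mean particle diameter in metres.
    density : float
        Particle mass density in kg m^-3.
    carbon_per_cell : float
        Carbon content per cell in g C.
    """

    name: str
    diameter: float
    density: float
    carbon_per_cell: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.carbon_per_cell < 0:
            raise ValueError("carbon_per_cell must be >= 0")


#: Airborne prokaryotes: 0.5 um mean diameter, 1.1 g cm^-3, 12.4 fg C cell^-1.
PROKARYOTE = ParticleClass("prokaryote", 0.5e-6, 1100.0, 12.4e-15)
#: Unicellular eukaryotes (mostly fungal spores): 5 um, 1.1 g cm^-3, 13 pg C.
EUKARYOTE = ParticleClass("eukaryote", 5.0e-6, 1100.0, 13.0e-12)


@dataclass(frozen=True)
class MeteoState:
    """Near-surface meteorology for one station or grid cell.

    u10 in m s^-1, T in K, RH in %, P in Pa, precip in mm h^-1 (0 = dry).
    """

    u10: float
    T: float
    RH: float
    P: float
    precip: float = 0.0

    def __post_init__(self) -> None:
        if self.u10 < 0:
            raise ValueError(f"u10 must be >= 0, got {self.u10}")
        if not 150.0 < self.T < 350.0:
            raise ValueError(f"T out of physical range (150, 350) K: {self.T}")
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError(f"RH out of [0, 100] %: {self.RH}")
        if self.P <= 0:
            raise ValueError(f"P must be > 0 Pa, got {self.P}")
        if self.precip < 0:
            raise ValueError("precip must be >= 0")


@dataclass(frozen=True)
class StationRecord:
    """One 6-h air/seawater sampling event along the cruise track."""

    id: str
    lat: float
    lon: float
    time: pd.Timestamp
    distance_to_land: float        # km
    meteo: MeteoState
    c_air_prok: float              # cells m^-3
    c_air_euk: float               # cells m^-3
    c_water_prok: float            # cells m^-3
    abl_height: float | None = None  # m

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if self.distance_to_land < 0:
            raise ValueError("distance_to_land must be >= 0")
        for name in ("c_air_prok", "c_air_euk", "c_water_prok"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.abl_height is not None and self.abl_height <= 0:
            raise ValueError("abl_height must be > 0 when given")
        # longitudes normalised to [-180, 180)
        object.__setattr__(self, "lon", ((self.lon + 180.0) % 360.0) - 180.0)


@dataclass(frozen=True)
class TrajectoryPath:
    """Forward air-mass trajectory: (elapsed seconds, lat, lon, altitude m)."""

    points: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("trajectory needs at least 2 points")
        t = [p[0] for p in self.points]
        if t[0] != 0.0:
            raise ValueError("trajectory must start at elapsed time 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("elapsed times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points])

    @property
    def lats(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points])

    @property
    def lons(self) -> np.ndarray:
        return np.asarray([p[2] for p in self.points])


@dataclass(frozen=True)
class ThetaProfile:
    """Vertical potential-temperature profile: (height m, theta K) pairs."""

    levels: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("profile needs at least 2 levels")
        z = [p[0] for p in self.levels]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ValueError("heights must be strictly increasing")

    @property
    def heights(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.levels])

    @property
    def theta(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.levels])


# --------------------------------------------------------------------------- #
# station tables
# --------------------------------------------------------------------------- #

#: Default column names and input units for station tables.
DEFAULT_DIALECT = {
    "columns": {
        "id": "id",
        "lat": "lat",
        "lon": "lon",
        "time": "time",
        "distance_to_land": "distance_to_land_km",
        "u10": "u10_m_s",
        "T": "air_temperature",
        "RH": "rh_pct",
        "P": "pressure",
        "precip": "precip_mm_h",
        "c_air_prok": "c_air_prok_m3",
        "c_air_euk": "c_air_euk_m3",
        "c_water_prok": "c_water_prok",
        "abl_height": "abl_height_m",
    },
    # accepted: temperature "C"|"K"; pressure "hPa"|"Pa"; water "per_ml"|"per_m3"
    "temperature_unit": "C",
    "pressure_unit": "hPa",
    "water_abundance_unit": "per_ml",
}

_MANDATORY = ("id", "lat", "lon", "distance_to_land", "u10", "T", "RH", "P",
              "c_air_prok", "c_air_euk", "c_water_prok")


def _merge_dialect(dialect: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v)
           for k, v in DEFAULT_DIALECT.items()}
    if dialect:
        for k, v in dialect.items():
            if k == "columns":
                out["columns"].update(v)
            else:
                out[k] = v
    return out


def read_stations(path, dialect: dict | None = None,
                  errors: list | None = None) -> list[StationRecord]:
    """Read a delimited station table into unit-normalised records.

    Rows violating a physical invariant (RH outside [0, 100], negative
    abundance, ...) or containing non-numeric cells are rejected; each
    rejection is logged with its 0-based row index and, when ``errors`` is
    passed, appended to it as ``(row_index, message)``.

    Raises
    ------
    ValueError
        If a mandatory column is missing from the header.
    """
    dia = _merge_dialect(dialect)
    cols = dia["columns"]
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        log.warning("station table %s is empty", path)
        return []

    missing = [cols[k] for k in _MANDATORY if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"station table missing mandatory columns: {missing}")

    records: list[StationRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(_row_to_record(row, dia))
        except (ValueError, TypeError) as exc:
            log.warning("station row %d rejected: %s", i, exc)
            if errors is not None:
                errors.append((i, str(exc)))
    return records


def _num(row, name, col) -> float:
    v = pd.to_numeric(row[col], errors="coerce")
    if pd.isna(v):
        raise ValueError(f"non-numeric value in field '{name}': {row[col]!r}")
    return float(v)


def _row_to_record(row: pd.Series, dia: dict) -> StationRecord:
    c = dia["columns"]
    T = _num(row, "T", c["T"])
    if dia.get("temperature_unit", "C") == "C":
        T += 273.15
    P = _num(row, "P", c["P"])
    if dia.get("pressure_unit", "hPa") == "hPa":
        P *= 100.0
    c_water = _num(row, "c_water_prok", c["c_water_prok"])
    if dia.get("water_abundance_unit", "per_ml") == "per_ml":
        c_water *= 1.0e6  # cells ml^-1 -> cells m^-3
    precip = 0.0
    if c["precip"] in row.index and not pd.isna(row[c["precip"]]):
        precip = _num(row, "precip", c["precip"])
    abl = None
    if c["abl_height"] in row.index and not pd.isna(row[c["abl_height"]]):
        abl = _num(row, "abl_height", c["abl_height"])
    time = pd.Timestamp(row[c["time"]]) if c["time"] in row.index else pd.Timestamp(0)
    meteo = MeteoState(u10=_num(row, "u10", c["u10"]), T=T,
                       RH=_num(row, "RH", c["RH"]), P=P, precip=precip)
    return StationRecord(
        id=str(row[c["id"]]),
        lat=_num(row, "lat", c["lat"]),
        lon=_num(row, "lon", c["lon"]),
        time=time,
        distance_to_land=_num(row, "distance_to_land", c["distance_to_land"]),
        meteo=meteo,
        c_air_prok=_num(row, "c_air_prok", c["c_air_prok"]),
        c_air_euk=_num(row, "c_air_euk", c["c_air_euk"]),
        c_water_prok=c_water,
    )


#: Dialect describing tables already written in internal (SI) units.
SI_DIALECT = {
    "temperature_unit": "K",
    "pressure_unit": "Pa",
    "water_abundance_unit": "per_m3",
}


def write_stations(records: Sequence[StationRecord], path) -> None:
    """Write records as CSV in internal (SI) units, round-trippable with
    ``read_stations(path, SI_DIALECT)`` to 12 significant digits."""
    cols = DEFAULT_DIALECT["columns"]
    rows = []
    for r in records:
        rows.append({
            cols["id"]: r.id, cols["lat"]: r.lat, cols["lon"]: r.lon,
            cols["time"]: r.time.isoformat(),
            cols["distance_to_land"]: r.distance_to_land,
            cols["u10"]: r.meteo.u10, cols["T"]: r.meteo.T,
            cols["RH"]: r.meteo.RH, cols["P"]: r.meteo.P,
            cols["precip"]: r.meteo.precip,
            cols["c_air_prok"]: r.c_air_prok, cols["c_air_euk"]: r.c_air_euk,
            cols["c_water_prok"]: r.c_water_prok,
            cols["abl_height"]: r.abl_height if r.abl_height is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------- #
# trajectories, coastlines, config
# --------------------------------------------------------------------------- #

def read_trajectory(path) -> TrajectoryPath:
    """Read a whitespace- or comma-delimited time/lat/lon/altitude file.

    Rows are sorted ascending by time, duplicate timestamps collapsed (first
    kept), and elapsed time rebased so the first point is at 0 s.
    """
    arr = np.atleast_2d(np.loadtxt(path, delimiter=None if _is_ws(path) else ","))
    if arr.shape[0] < 2:
        raise ValueError("trajectory file must contain at least 2 points")
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    _, first = np.unique(arr[:, 0], return_index=True)
    arr = arr[first]
    if arr.shape[0] < 2:
        raise ValueError("trajectory collapsed to fewer than 2 distinct times")
    arr[:, 0] -= arr[0, 0]
    return TrajectoryPath(tuple(map(tuple, arr[:, :4])))


def _is_ws(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "," not in line
    return True


def read_coastline(path):
    """Read coastline geometry from a GeoJSON file (polygons or points)."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        from shapely.ops import unary_union
        return unary_union([shape(f["geometry"]) for f in gj["features"]])
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def write_coastline(geom, path) -> None:
    from shapely.geometry import mapping

    with open(path, "w") as fh:
        json.dump({"type": "Feature", "properties": {},
                   "geometry": mapping(geom)}, fh)


def load_config(path) -> dict:
    """Load a YAML configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
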