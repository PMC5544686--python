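"""Boundary-layer and transport quantities.

The atmospheric boundary layer (ABL) is the well-mixed layer whose height H
sets the airborne column load (cells m^-2 = abundance x H).  A well-mixed
column drained only by dry deposition at velocity v_d loses cells as
R(t) = exp(-v_d t / H); the residence half-time t50 = H ln2 / v_d is the time
for half the load to settle.  Combined with a forward air-mass trajectory,
the maximum great-circle excursion from the origin within t50 measures how
far half of the microbes can be carried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core_io import ThetaProfile, TrajectoryPath
from .geo import haversine_km

__all__ = [
    "OCEAN_MEAN_ABL_M",
    "LAND_MEAN_ABL_M",
    "ResidenceResult",
    "TransportDistance",
    "abl_height",
    "column_load",
    "remaining_fraction",
    "residence_half_time",
    "transport_distance",
]

#: Climatological mean ABL height over the ocean (m), used when no profile
#: or reanalysis value is available for a station.
OCEAN_MEAN_ABL_M = 817.0
#: Climatological mean ABL height over land (m).
LAND_MEAN_ABL_M = 564.0

SECONDS_PER_DAY = 86400.0


class TransportDistance(NamedTuple):
    distance_km: float
    truncated: bool  # trajectory ended before t50 was reached


@dataclass(frozen=True)
class ResidenceResult:
    """Residence half-time and, when a trajectory is given, the transport
    range of the longest-lived half of the load."""

    t50: float                         # s
    v_d: float                         # m s^-1
    abl_height: float                  # m
    transport_distance: float | None = None  # km
    truncated: bool = False

    @property
    def t50_days(self) -> float:
        return self.t50 / SECONDS_PER_DAY


def abl_height(profile: ThetaProfile, delta: float = 2.0) -> float:
    """ABL height (m): lowest height where the potential temperature first
    reaches its profile minimum plus ``delta`` K, linearly interpolated
    between levels.

    Raises
    ------
    ValueError
        If the threshold is never reached within the profile (e.g. a
        constant profile); the caller may extend the profile upward.
    """
    z = profile.heights
    th = profile.theta
    threshold = th.min() + delta
    if th[0] >= threshold:
        return float(z[0])
    for i in range(1, len(z)):
        if th[i] >= threshold:
            frac = (threshold - th[i - 1]) / (th[i] - th[i - 1])
            return float(z[i - 1] + frac * (z[i] - z[i - 1]))
    raise ValueError(
        f"theta never reaches min + {delta} K within the profile "
        f"(top {z[-1]} m)")


def column_load(c_air: float, abl_height_m: float) -> float:
    """Column microbial load (cells m^-2) of a well-mixed boundary layer."""
    if c_air < 0 or abl_height_m < 0:
        raise ValueError("inputs must be >= 0")
    return c_air * abl_height_m


def remaining_fraction(t: float, v_d: float, abl_height_m: float) -> float:
    """Fraction of the initial column load still airborne after time t (s):
    exp(-v_d t / H) for a well-mixed column drained by deposition."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if abl_height_m <= 0:
        raise ValueError("abl_height must be > 0")
    return math.exp(-v_d * t / abl_height_m)


def residence_half_time(v_d: float, abl_height_m: float) -> float:
    """Time (s) for half the column load to deposit: t50 = H ln2 / v_d."""
    if abl_height_m <= 0:
        raise ValueError("abl_height must be > 0")
    if v_d <= 0:
        raise ZeroDivisionError("v_d must be > 0 for a finite residence time")
    return abl_height_m * math.log(2.0) / v_d


def transport_distance(traj: TrajectoryPath, t50: float) -> TransportDistance:
    """Maximum great-circle distance (km) from the trajectory origin over all
    points with elapsed time <= t50.

    The point at t50 itself is included by linear interpolation of the
    coordinates when the trajectory brackets it.  If the trajectory ends
    before t50 the maximum over the whole path is returned with
    ``truncated=True``.
    """
    if t50 < 0:
        raise ValueError("t50 must be >= 0")
    t = traj.times
    lat = traj.lats
    lon = traj.lons
    truncated = t[-1] < t50
    if truncated:
        sel_lat, sel_lon = lat, lon
    else:
        mask = t <= t50
        sel_lat, sel_lon = lat[mask], lon[mask]
        if t[mask].size and t[mask][-1] < t50:
            # interpolate the position at exactly t50
            j = int(np.searchsorted(t, t50))
            f = (t50 - t[j - 1]) / (t[j] - t[j - 1])
            sel_lat = np.append(sel_lat, lat[j - 1] + f * (lat[j] - lat[j - 1]))
            sel_lon = np.append(sel_lon, lon[j - 1] + f * (lon[j] - lon[j - 1]))
    d = haversine_km(lat[0], lon[0], sel_lat, sel_lon)
    return TransportDistance(float(np.max(d)), bool(truncated))
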