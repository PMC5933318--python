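"""Great-circle distances and solar geometry.

Distances use the haversine formula on a sphere of radius 6371 km, the
convention used for whale-track movement descriptors throughout this
package.  Day/night tagging uses geometric solar elevation (no twilight
or refraction allowance): a time/place is "day" iff the sun's centre is
above the horizon.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or numpy arrays (broadcasting).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    # wrap longitude difference onto (-pi, pi] so antimeridian crossings
    # measure the short way round
    dlon = np.mod(lon2 - lon1 + np.pi, 2 * np.pi) - np.pi
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def track_length_km(lons, lats) -> float:
    """Summed haversine length of a polyline given as degree arrays."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 2:
        return 0.0
    return float(np.sum(haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])))


def _julian_day(t: datetime) -> float:
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return t.timestamp() / 86400.0 + 2440587.5


def solar_elevation_deg(t: datetime, lon: float, lat: float) -> float:
    """Geometric solar elevation angle in degrees.

    Low-precision NOAA-style ephemeris: mean solar anomaly + equation of
    centre for the sun's ecliptic longitude, obliquity-rotated to
    declination/right ascension, and the local hour angle from apparent
    sidereal time.  Accurate to well under 0.1 degree for current decades,
    far tighter than the day/night decision needs.
    """
    jd = _julian_day(t)
    n = jd - 2451545.0  # days since J2000.0
    # mean longitude and mean anomaly of the sun (degrees)
    L = (280.460 + 0.9856474 * n) % 360.0
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    # ecliptic longitude with equation of centre
    lam = math.radians(L + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * n)  # obliquity
    decl = math.asin(math.sin(eps) * math.sin(lam))
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    # Greenwich mean sidereal time (degrees) -> local hour angle
    gmst = (280.46061837 + 360.98564736629 * n) % 360.0
    ha = math.radians((gmst + lon) % 360.0) - ra
    lat_r = math.radians(lat)
    sin_el = (math.sin(lat_r) * math.sin(decl)
              + math.cos(lat_r) * math.cos(decl) * math.cos(ha))
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))


def is_daylight(t: datetime, lon: float, lat: float) -> bool:
    """True iff geometric solar elevation is positive (sun above horizon)."""
    return solar_elevation_deg(t, lon, lat) > 0.0
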