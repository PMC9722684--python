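"""Spherical-earth geometry helpers.

All distances are kilometres unless noted; bearings are degrees clockwise
from north. Positions are WGS84 lat/lon treated as spherical with
R = 6371 km — the matching gates here (200 nmi candidate radius, km-scale
rasters) are far coarser than the spherical approximation error.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_NMI = 1.852


def nmi_to_km(nmi):
    return np.asarray(nmi) * KM_PER_NMI


def km_to_nmi(km):
    return np.asarray(km) / KM_PER_NMI


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance between points, vectorised."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination(lat, lon, bearing_deg, dist_km):
    """Point reached travelling `dist_km` along `bearing_deg` on the sphere."""
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    brg = np.radians(bearing_deg)
    delta = np.asarray(dist_km) / EARTH_RADIUS_KM
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    return np.degrees(lat2), (np.degrees(lon2) + 180.0) % 360.0 - 180.0


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return (np.degrees(np.arctan2(y, x)) + 360.0) % 360.0


def to_local_en(lat0, lon0, lat, lon):
    """Project points to a local azimuthal-equidistant east/north plane (km).

    The plane is tangent at (lat0, lon0): each point maps to
    (d·sin β, d·cos β) where d is great-circle distance and β the initial
    bearing from the origin. Exact in range/azimuth, adequate for the
    ≤ ~100 km frames used by the rasters.
    """
    d = haversine_km(lat0, lon0, lat, lon)
    b = np.radians(initial_bearing(lat0, lon0, lat, lon))
    return d * np.sin(b), d * np.cos(b)


def from_local_en(lat0, lon0, east_km, north_km):
    """Inverse of :func:`to_local_en`."""
    east_km = np.asarray(east_km, dtype=float)
    north_km = np.asarray(north_km, dtype=float)
    d = np.hypot(east_km, north_km)
    b = np.degrees(np.arctan2(east_km, north_km))
    return destination(lat0, lon0, b, d)
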