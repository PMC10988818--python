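"""Great-circle geometry on a spherical Earth.

All distances use a 6371-km sphere, so one degree of latitude spans
111.19 km.  Longitudes are degrees east, latitudes degrees north (WGS84
coordinates treated as spherical).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = np.pi / 180.0 * EARTH_RADIUS_KM  # 111.1949... km per degree of arc


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Vectorized: accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2.

    Returns degrees clockwise from true north in [0, 360).  Antipodal
    (or coincident) point pairs have no defined bearing and raise
    ``ValueError`` — callers must guard degenerate steps themselves.
    """
    lon1a, lat1a, lon2a, lat2a = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2a - lon1a
    x = np.sin(dlon) * np.cos(lat2a)
    y = np.cos(lat1a) * np.sin(lat2a) - np.sin(lat1a) * np.cos(lat2a) * np.cos(dlon)
    dist = haversine_km(lon1, lat1, lon2, lat2)
    bad = np.abs(dist - np.pi * EARTH_RADIUS_KM) < 1.0
    if np.any(bad):
        raise ValueError("bearing undefined for (nearly) antipodal points")
    return np.mod(np.degrees(np.arctan2(x, y)), 360.0)


def destination(lon, lat, bearing_deg, distance_km):
    """Destination point from start, initial bearing and great-circle distance."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    d = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(d) * np.cos(lat1),
        np.cos(d) - np.sin(lat1) * np.sin(lat2),
    )
    lon_out = np.degrees(lon2)
    lon_out = np.mod(lon_out + 180.0, 360.0) - 180.0
    return lon_out, np.degrees(lat2)
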