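"""Wind annotation of movement steps: Δangle and tail-wind component.

Conventions.  The u/v wind components define the direction the wind blows
TOWARD (the "to" convention used by reanalysis products); Δangle is the
absolute angular difference between the bird's direction of movement and
that to-direction, folded to [0°, 180°], so 0° is a pure tailwind and 180°
a pure headwind.  The signed tail-wind component is

    TWC = wind_speed · cos(Δangle)        (km h⁻¹ after ×3.6)

— positive with tailwinds, negative against headwinds, and TWC² plus the
crosswind component squared recovers the wind speed squared.  Wind is
stored in m s⁻¹ and converted with the ×3.6 factor when compared with
ground speeds in km h⁻¹.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from petrelwind.geo import haversine_km, initial_bearing
from petrelwind.tracks import Trip

MS_TO_KMH = 3.6


class OutOfDomainError(ValueError):
    """A query point lies outside the wind grid hull."""


class WindSampler:
    """Trilinear (lon, lat, time) interpolator over a gridded wind field."""

    def __init__(self, field: xr.Dataset):
        t = field["time"].values.astype("datetime64[s]").astype(np.int64)
        lat = field["lat"].values
        lon = field["lon"].values
        self._t0 = t[0]
        self._u = RegularGridInterpolator(
            (t - t[0], lat, lon), field["u10"].values.astype(float), bounds_error=True
        )
        self._v = RegularGridInterpolator(
            (t - t[0], lat, lon), field["v10"].values.astype(float), bounds_error=True
        )

    def sample(self, lon, lat, time):
        """Wind (u, v) in m s⁻¹ at arbitrary points inside the grid hull."""
        idx = pd.to_datetime(np.atleast_1d(np.asarray(time)))
        tsec = ((idx - pd.Timestamp("1970-01-01")) // pd.Timedelta(seconds=1)).to_numpy() - self._t0
        pts = np.column_stack(
            [tsec, np.atleast_1d(np.asarray(lat, float)), np.atleast_1d(np.asarray(lon, float))]
        )
        try:
            u = self._u(pts)
            v = self._v(pts)
        except ValueError as exc:
            raise OutOfDomainError(f"wind query outside grid hull: {exc}") from None
        if np.isscalar(lon) or np.asarray(lon).ndim == 0:
            return float(u[0]), float(v[0])
        return u, v


def sample_wind(field: xr.Dataset, lon, lat, time):
    """One-shot trilinear wind sample; build a :class:`WindSampler` for many."""
    return WindSampler(field).sample(lon, lat, time)


def step_bearing(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Initial great-circle bearing of the step p1→p2, degrees in [0, 360)."""
    return float(initial_bearing(p1[0], p1[1], p2[0], p2[1]))


def delta_angle(bearing, wind_to_direction):
    """Angle between movement direction and wind to-direction, folded to [0, 180].

    0° means the wind blows exactly along the movement (tailwind); 180°
    means it blows exactly against it (headwind).
    """
    d = np.abs(np.mod(np.asarray(bearing, float) - np.asarray(wind_to_direction, float) + 180.0, 360.0) - 180.0)
    return d if d.ndim else float(d)


def tail_wind_component(wind_speed, delta_angle_deg):
    """Signed wind-speed component along the movement direction.

    Same units as ``wind_speed``; positive for tailwinds, negative for
    headwinds, and never exceeding the wind speed in magnitude.
    """
    out = np.asarray(wind_speed, float) * np.cos(np.radians(np.asarray(delta_angle_deg, float)))
    return out if out.ndim else float(out)


def wind_to_from(direction_deg):
    """Convert between to- and from- wind direction conventions (±180°)."""
    return np.mod(np.asarray(direction_deg, float) + 180.0, 360.0)


def annotate_trip(trip: Trip, sampler: WindSampler | xr.Dataset) -> pd.DataFrame:
    """Per-step wind annotation of a regular-resolution trip.

    Each step runs from position i to i+1 and is annotated with its
    length, ground speed, bearing, the wind sampled at the step's start
    position and start time, Δangle and the signed TWC (both wind speed
    and TWC reported in km h⁻¹ alongside m s⁻¹).  Pure per-step function
    of (step, field): row order does not matter.
    """
    if isinstance(sampler, xr.Dataset):
        sampler = WindSampler(sampler)
    d = trip.data
    lon0, lat0 = d["lon"].values[:-1], d["lat"].values[:-1]
    lon1, lat1 = d["lon"].values[1:], d["lat"].values[1:]
    step_km = haversine_km(lon0, lat0, lon1, lat1)
    moving = step_km > 1e-9
    bearing = np.full(step_km.shape, np.nan)
    if moving.any():
        bearing[moving] = initial_bearing(lon0[moving], lat0[moving], lon1[moving], lat1[moving])
    u, v = sampler.sample(lon0, lat0, d["timestamp"].values[:-1])
    wind_speed = np.hypot(u, v)
    wind_to = np.mod(np.degrees(np.arctan2(u, v)), 360.0)
    dang = delta_angle(bearing, wind_to)
    twc_ms = tail_wind_component(wind_speed, dang)
    out = pd.DataFrame(
        {
            "trip_id": trip.trip_id,
            "bird_id": trip.bird_id,
            "timestamp": d["timestamp"].values[:-1],
            "lon": lon0,
            "lat": lat0,
            "step_length_km": step_km,
            "ground_speed_kmh": step_km / trip.resolution_hours,
            "bearing_deg": bearing,
            "u_ms": u,
            "v_ms": v,
            "wind_speed_ms": wind_speed,
            "wind_speed_kmh": wind_speed * MS_TO_KMH,
            "wind_to_direction_deg": wind_to,
            "delta_angle_deg": dang,
            "twc_ms": twc_ms,
            "twc_kmh": twc_ms * MS_TO_KMH,
        }
    )
    out["resolution_hours"] = trip.resolution_hours
    return out


def annotate_fleet(trips: list[Trip], field: xr.Dataset) -> pd.DataFrame:
    sampler = WindSampler(field)
    return pd.concat([annotate_trip(t, sampler) for t in trips], ignore_index=True)
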