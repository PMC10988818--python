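"""Track regularization, trip splitting and long/short trip classification.

Raw tracking fixes are linearly interpolated onto an exact 1-h or 2-h time
grid (positions interpolated in lon/lat directly — tracks are far from the
poles, and the distortion at these scales is negligible), trips are split
where the distance to the colony crosses a radius, and trips are assigned
to "long"/"short" classes by 2-means clustering on (maximum colony
distance, duration); only long trips feed the downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from petrelwind.geo import haversine_km


class TrackGapError(ValueError):
    """A raw track has a temporal gap too wide to interpolate across."""


class DegenerateTripsError(ValueError):
    """Trips are indistinguishable; 2-means classification is meaningless."""


@dataclass
class Trip:
    """One colony-anchored foraging trip on a regular time grid."""

    trip_id: str
    bird_id: str
    data: pd.DataFrame  # timestamp, lon, lat, imputed
    resolution_hours: float
    colony: tuple[float, float] | None = None
    trip_class: str | None = None

    def __post_init__(self) -> None:
        dt = self.data["timestamp"].diff().dropna()
        if len(dt) and not np.allclose(dt / pd.Timedelta(hours=1), self.resolution_hours):
            raise ValueError("trip timestamps are not on the stated regular grid")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration_days(self) -> float:
        t = self.data["timestamp"]
        return (t.iloc[-1] - t.iloc[0]) / pd.Timedelta(days=1)

    @property
    def cumulative_distance_km(self) -> float:
        d = self.data
        return float(
            haversine_km(d["lon"].values[:-1], d["lat"].values[:-1], d["lon"].values[1:], d["lat"].values[1:]).sum()
        )

    @property
    def max_colony_distance_km(self) -> float:
        if self.colony is None:
            raise ValueError("trip has no colony reference")
        d = self.data
        return float(haversine_km(d["lon"].values, d["lat"].values, self.colony[0], self.colony[1]).max())

    @property
    def imputed_fraction(self) -> float:
        return float(self.data["imputed"].mean())

    def summary(self) -> dict:
        return {
            "trip_id": self.trip_id,
            "bird_id": self.bird_id,
            "n_points": len(self),
            "resolution_hours": self.resolution_hours,
            "duration_days": self.duration_days,
            "cumulative_distance_km": self.cumulative_distance_km,
            "max_colony_distance_km": self.max_colony_distance_km if self.colony else np.nan,
            "imputed_fraction": self.imputed_fraction,
            "trip_class": self.trip_class,
        }


def trip_summary_table(trips: list[Trip]) -> pd.DataFrame:
    """Per-trip summary (duration, cumulative and max colony distance, class)."""
    return pd.DataFrame([t.summary() for t in trips])


def interpolate_track(
    raw_points: pd.DataFrame,
    target_resolution: float,
    trip_id: str = "trip0",
    bird_id: str = "bird0",
    colony: tuple[float, float] | None = None,
    max_gap_hours: float = 12.0,
) -> Trip:
    """Linearly interpolate raw fixes to a regular 1-h or 2-h grid.

    Output timestamps fall on exact multiples of the resolution (whole
    hours of the day); positions between bracketing fixes are linear in
    lon/lat; points without a raw fix at their exact timestamp are
    flagged imputed.  Interpolation never extrapolates: the grid spans
    [ceil(first fix), floor(last fix)].  A gap between consecutive raw
    fixes wider than ``max_gap_hours`` rejects the whole trip.
    """
    if target_resolution not in (1, 2):
        raise ValueError("target_resolution must be 1 or 2 hours")
    raw = raw_points.sort_values("timestamp").reset_index(drop=True)
    if len(raw) < 2:
        raise ValueError("need at least 2 raw fixes")
    ts = pd.to_datetime(raw["timestamp"])
    gaps = ts.diff().dropna() / pd.Timedelta(hours=1)
    if (gaps <= 0).any():
        raise ValueError("raw timestamps must be strictly increasing")
    if (gaps > max_gap_hours).any():
        worst = float(gaps.max())
        raise TrackGapError(f"trip {trip_id}: raw gap of {worst:.1f} h exceeds max of {max_gap_hours} h")

    step = pd.Timedelta(hours=target_resolution)
    t0 = ts.iloc[0].ceil(step)
    t1 = ts.iloc[-1].floor(step)
    if t1 < t0:
        raise ValueError("track too short for the requested resolution")
    grid = pd.date_range(t0, t1, freq=step)

    tsec = (ts - ts.iloc[0]) / pd.Timedelta(seconds=1)
    gsec = (grid - ts.iloc[0]) / pd.Timedelta(seconds=1)
    lon = np.interp(gsec, tsec, raw["lon"].values)
    lat = np.interp(gsec, tsec, raw["lat"].values)
    have_fix = np.isin(grid.round("s").asi8, ts.dt.round("s").astype(np.int64))
    df = pd.DataFrame({"timestamp": grid, "lon": lon, "lat": lat, "imputed": ~have_fix})
    return Trip(trip_id=trip_id, bird_id=bird_id, data=df, resolution_hours=float(target_resolution), colony=colony)


def resample_to_2h(trip: Trip) -> Trip:
    """Keep every second position of a 1-h trip (first point retained)."""
    if trip.resolution_hours != 1:
        raise ValueError("resample_to_2h expects a 1-h resolution trip")
    df = trip.data.iloc[::2].reset_index(drop=True)
    return Trip(
        trip_id=trip.trip_id,
        bird_id=trip.bird_id,
        data=df,
        resolution_hours=2.0,
        colony=trip.colony,
        trip_class=trip.trip_class,
    )


def split_trips(
    raw: pd.DataFrame,
    colony: tuple[float, float],
    radius_km: float = 5.0,
    min_points: int = 2,
) -> list[pd.DataFrame]:
    """Split a continuous position series into colony-anchored trips.

    A trip runs from the last fix inside the colony radius before an
    excursion to the first fix back inside it.
    """
    raw = raw.sort_values("timestamp").reset_index(drop=True)
    dist = haversine_km(raw["lon"].values, raw["lat"].values, colony[0], colony[1])
    inside = dist <= radius_km
    trips = []
    start = None
    for i in range(len(raw)):
        if inside[i]:
            if start is not None and i - start + 1 >= min_points:
                trips.append(raw.iloc[start : i + 1].reset_index(drop=True))
            start = i
        elif start is None:
            start = i  # series begins at sea: open trip from first fix
    return trips


def classify_trips(trips: list[Trip], seed: int = 0, n_init: int = 10) -> tuple[list[str], np.ndarray]:
    """Assign each trip to a "long" or "short" class by 2-means.

    Features are (max colony distance, duration), each standardized to
    zero mean and unit variance, so the labels are invariant to any
    positive rescaling of either feature.  The cluster whose centroid is
    farther from the origin in original units (km, days) is "long".
    Labels are written onto the trips and returned with the centroids
    (in original units).
    """
    if len(trips) < 2:
        raise ValueError("need at least 2 trips to classify")
    X = np.array([[t.max_colony_distance_km, t.duration_days] for t in trips], dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0) and np.allclose(X, X[0]):
        raise DegenerateTripsError("all trips identical; cannot split long/short")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(Z)
    centroids = km.cluster_centers_ * sd + X.mean(axis=0)  # back to km / days
    long_cluster = int(np.argmax(np.linalg.norm(centroids, axis=1)))
    labels = ["long" if lab == long_cluster else "short" for lab in km.labels_]
    for t, lab in zip(trips, labels):
        t.trip_class = lab
    return labels, centroids


def filter_long(trips: list[Trip]) -> list[Trip]:
    """Retain long trips only, logging the share of at-sea time removed."""
    if any(t.trip_class is None for t in trips):
        raise ValueError("classify_trips must run before filter_long")
    long_trips = [t for t in trips if t.trip_class == "long"]
    total = sum(t.duration_days for t in trips)
    kept = sum(t.duration_days for t in long_trips)
    removed_pct = 100.0 * (1.0 - kept / total) if total > 0 else 0.0
    if not long_trips:
        warnings.warn("no long trips retained", stacklevel=2)
    else:
        import logging

        logging.getLogger(__name__).info(
            "retained %d/%d trips (removed %.1f%% of at-sea time)", len(long_trips), len(trips), removed_pct
        )
    return long_trips
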