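"""Counterfactual flight-performance simulation: track-swap and season-swap.

The engine asks whether a species' breeding windscape explains its
movement schedule.  For a focal species with a fitted speed-wind surface,
four scenarios cross (own | other) track geometry with (own | other)
breeding season.  Step geometry is never altered: each observed transit
step keeps its length and bearing, wind is sampled at the step's location
and (possibly season-shifted) time, Δangle is recomputed against the
counterfactual wind, ground speed is predicted from the focal species'
surface, and the trip duration is the sum of step length / predicted
speed.  The percent change in duration is referenced to the mean observed
transit duration of the focal species' real trips, and scenarios are
compared with Welch two-sample t-tests on per-trip durations.

Season shifts support two modes: a whole-calendar-month offset (e.g.
±2 months), or the day offset between the two species' incubation
date-windows (the default pairing used by the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from petrelwind.wind import MS_TO_KMH, WindSampler, delta_angle
from petrelwind.windgam import WindSpeedGAMResults


@dataclass
class Scenario:
    """One cell of the (track × season) counterfactual grid."""

    focal_species: str
    track_source: str  # "own" | "other"
    season: str  # "own" | "other"
    season_shift_months: int = 0  # calendar months added to timestamps
    season_shift_days: float | None = None  # overrides months when set

    def __post_init__(self) -> None:
        if self.track_source not in ("own", "other") or self.season not in ("own", "other"):
            raise ValueError("track_source and season must be 'own' or 'other'")
        if self.season == "own" and (self.season_shift_months or self.season_shift_days):
            raise ValueError("own-season scenarios take no time shift")

    @property
    def name(self) -> str:
        return f"{self.season} season, {self.track_source} track"


def incubation_window_shift(own_start: str, other_start: str) -> float:
    """Day offset mapping the focal species' incubation onto the other's.

    E.g. an own window starting 19 June and an other window starting
    28 August give a +70-day shift.
    """
    return (pd.Timestamp(other_start) - pd.Timestamp(own_start)) / pd.Timedelta(days=1)


@dataclass
class ScenarioResult:
    """Per-trip simulated transit durations for one scenario."""

    scenario: Scenario
    per_trip: pd.DataFrame  # trip_id, duration_h, mean_speed_kmh, distance_km, pct_change
    reference_duration_h: float
    excluded_trips: list = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return self.per_trip["duration_h"].to_numpy()

    @property
    def mean_pct_change(self) -> float:
        return float(self.per_trip["pct_change"].mean())

    def summary(self) -> str:
        return (
            f"scenario [{self.scenario.name}] (focal {self.scenario.focal_species}): "
            f"{len(self.per_trip)} trips, mean duration {self.durations.mean():.1f} h, "
            f"mean change vs own real trips {self.mean_pct_change:+.1f}%"
            + (f", {len(self.excluded_trips)} trips excluded" if self.excluded_trips else "")
        )


def observed_transit_durations(decoded: pd.DataFrame) -> pd.Series:
    """Observed transit duration (h) per trip: transit steps × resolution."""
    transit = decoded[decoded["state"] == 1]
    return transit.groupby("trip_id")["resolution_hours"].sum()


def run_scenario(
    scenario: Scenario,
    tracks: pd.DataFrame,
    windfield,
    gam_fit: WindSpeedGAMResults,
    reference_duration_h: float | None = None,
    min_speed_kmh: float = 1.0,
    observed_speeds: bool = False,
) -> ScenarioResult:
    """Simulate the transit portions of ``tracks`` under one scenario.

    ``tracks`` is a decoded annotated-step table (``state`` column, 1 =
    transit) of the scenario's source species; ``gam_fit`` is the focal
    species' speed-wind surface; ``reference_duration_h`` is the mean
    observed transit duration of the focal species' real trips (computed
    from ``tracks`` when the scenario is own-track and not supplied).
    Trips containing a predicted speed below ``min_speed_kmh`` are
    excluded with a diagnostic.  With ``observed_speeds=True`` the
    surface is bypassed and observed ground speeds are used (the own-own
    consistency cell).
    """
    transit = tracks[tracks["state"] == 1].copy()
    if transit.empty:
        raise ValueError("no transit steps in input")
    if reference_duration_h is None:
        if scenario.track_source != "own" or scenario.season != "own":
            raise ValueError("reference duration must be supplied for counterfactual scenarios")
        reference_duration_h = float(observed_transit_durations(tracks).mean())

    times = pd.to_datetime(transit["timestamp"])
    if scenario.season_shift_days is not None:
        times = times + pd.Timedelta(days=scenario.season_shift_days)
    elif scenario.season_shift_months:
        times = times + pd.DateOffset(months=scenario.season_shift_months)
    sampler = windfield if isinstance(windfield, WindSampler) else WindSampler(windfield)
    u, v = sampler.sample(transit["lon"].values, transit["lat"].values, times.values)
    wind_kmh = np.hypot(u, v) * MS_TO_KMH
    wind_to = np.mod(np.degrees(np.arctan2(u, v)), 360.0)
    dang = delta_angle(transit["bearing_deg"].values, wind_to)
    if observed_speeds:
        speed = transit["ground_speed_kmh"].to_numpy()
    else:
        speed = gam_fit.predict(dang, wind_kmh, warn_extrapolation=False)
    transit["sim_speed_kmh"] = speed
    transit["sim_duration_h"] = transit["step_length_km"].values / np.maximum(speed, 1e-12)

    rows, excluded = [], []
    for trip_id, g in transit.groupby("trip_id"):
        if (g["sim_speed_kmh"] < min_speed_kmh).any():
            excluded.append(
                {"trip_id": trip_id, "reason": f"predicted speed below {min_speed_kmh} km/h on some step"}
            )
            continue
        dist = float(g["step_length_km"].sum())
        dur = float(g["sim_duration_h"].sum())
        rows.append(
            {
                "trip_id": trip_id,
                "distance_km": dist,
                "duration_h": dur,
                "mean_speed_kmh": dist / dur,
                "pct_change": 100.0 * (dur - reference_duration_h) / reference_duration_h,
            }
        )
    if not rows:
        raise ValueError("all trips excluded from scenario")
    return ScenarioResult(
        scenario=scenario,
        per_trip=pd.DataFrame(rows),
        reference_duration_h=reference_duration_h,
        excluded_trips=excluded,
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p: float

    def __str__(self) -> str:
        return f"Welch t = {self.t:.3f}, d.f. = {self.df:.1f}, p = {self.p:.4g}"


def compare_scenarios(res_a: ScenarioResult | np.ndarray, res_b: ScenarioResult | np.ndarray) -> WelchResult:
    """Welch two-sample t-test on per-trip simulated durations.

    Unequal variances, Welch-Satterthwaite degrees of freedom, two-sided
    p-value.  Two identical constant samples compare as t = 0, p = 1.
    """
    a = res_a.durations if isinstance(res_a, ScenarioResult) else np.asarray(res_a, dtype=float)
    b = res_b.durations if isinstance(res_b, ScenarioResult) else np.asarray(res_b, dtype=float)
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
    r = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(r.statistic), df=float(r.df), p=float(r.pvalue))


def duration_boxplot_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Quartile summary of per-trip % duration change, one row per scenario."""
    if not results:
        raise ValueError("no scenario results")
    rows = []
    for res in results:
        if res.per_trip.empty:
            raise ValueError(f"scenario {res.scenario.name} holds no trips")
        x = res.per_trip["pct_change"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append(
            {
                "focal_species": res.scenario.focal_species,
                "scenario": res.scenario.name,
                "n_trips": len(x),
                "min": float(x.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(x.max()),
                "mean": float(x.mean()),
            }
        )
    return pd.DataFrame(rows)
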