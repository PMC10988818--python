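"""Track-swap / season-swap counterfactual engine."""

import numpy as np
import pandas as pd
import pytest

from petrelwind.scenarios import (
    Scenario,
    compare_scenarios,
    duration_boxplot_table,
    incubation_window_shift,
    observed_transit_durations,
    run_scenario,
)
from petrelwind.synthetic import WorldConfig, make_windfield
from petrelwind.windgam import fit_wind_gam


@pytest.fixture(scope="module")
def decoded_tracks(annotated):
    """Annotated fleet with every step treated as transit."""
    d = annotated.copy()
    d["state"] = 1
    return d


@pytest.fixture(scope="module")
def gam_fit(decoded_tracks):
    return fit_wind_gam(decoded_tracks, ar1=False)


class TestRunScenario:
    def test_own_own_with_observed_speeds_is_exactly_zero(self, decoded_tracks, windfield, gam_fit):
        res = run_scenario(Scenario("A", "own", "own"), decoded_tracks, windfield, gam_fit, observed_speeds=True)
        assert res.mean_pct_change == pytest.approx(0.0, abs=1e-9)
        # each trip's simulated duration equals its observed duration
        obs = observed_transit_durations(decoded_tracks)
        for _, row in res.per_trip.iterrows():
            assert row["duration_h"] == pytest.approx(obs[row["trip_id"]], rel=1e-9)

    def test_distance_conserved_in_every_scenario(self, decoded_tracks, windfield, gam_fit):
        ref = float(observed_transit_durations(decoded_tracks).mean())
        for sc in (Scenario("A", "own", "own"), Scenario("A", "own", "other", season_shift_months=2)):
            res = run_scenario(sc, decoded_tracks, windfield, gam_fit, reference_duration_h=ref)
            sim_dist = res.per_trip["distance_km"].sum()
            obs_dist = decoded_tracks.loc[decoded_tracks["state"] == 1, "step_length_km"].sum()
            assert sim_dist == pytest.approx(obs_dist, rel=1e-12)

    def test_doubled_track_length_doubles_duration(self, decoded_tracks, windfield, gam_fit):
        """Other-species tracks with 2x the summed step length and identical
        predicted speeds take exactly +100% duration (arithmetic oracle)."""
        ref = float(observed_transit_durations(decoded_tracks).mean())

        class ConstantSurface:
            def predict(self, d, w, warn_extrapolation=False):
                return np.full(np.broadcast(np.asarray(d), np.asarray(w)).shape, 20.0)

        doubled = decoded_tracks.copy()
        doubled["step_length_km"] = doubled["step_length_km"] * 2.0
        own = run_scenario(
            Scenario("A", "own", "own"), decoded_tracks, windfield, ConstantSurface(), reference_duration_h=None
        )
        other = run_scenario(
            Scenario("A", "other", "own"),
            doubled,
            windfield,
            ConstantSurface(),
            reference_duration_h=float(own.per_trip["duration_h"].mean()),
        )
        assert other.mean_pct_change == pytest.approx(100.0, rel=1e-9)

    def test_season_shift_in_seasonless_wind_changes_nothing(self, world, decoded_tracks, gam_fit):
        flat = make_windfield(WorldConfig(rng_seed=1, n_days=730), mean_speed=8.0, seasonal_amplitude=0.0)
        ref = float(observed_transit_durations(decoded_tracks).mean())
        own = run_scenario(Scenario("A", "own", "own"), decoded_tracks, flat, gam_fit, reference_duration_h=ref)
        shifted = run_scenario(
            Scenario("A", "own", "other", season_shift_months=2),
            decoded_tracks,
            flat,
            gam_fit,
            reference_duration_h=ref,
        )
        np.testing.assert_allclose(
            own.per_trip["duration_h"].to_numpy(), shifted.per_trip["duration_h"].to_numpy(), atol=1e-6
        )

    def test_slow_speed_trips_excluded_with_diagnostic(self, decoded_tracks, windfield):
        class CrawlSurface:
            def predict(self, d, w, warn_extrapolation=False):
                return np.full(np.broadcast(np.asarray(d), np.asarray(w)).shape, 0.5)

        with pytest.raises(ValueError, match="excluded"):
            run_scenario(
                Scenario("A", "own", "own"), decoded_tracks, windfield, CrawlSurface(), reference_duration_h=None
            )

    def test_incubation_window_shift_days(self):
        assert incubation_window_shift("2019-06-19", "2019-08-28") == 70.0
        assert incubation_window_shift("2019-08-28", "2019-06-19") == -70.0


class TestWelch:
    def test_textbook_samples(self):
        # closed-form oracle: {1,2,3} vs {4,5,6} has t = -3/sqrt(2/3), df = 4
        r = compare_scenarios(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert r.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert r.df == pytest.approx(4.0)

    def test_identical_samples_t_zero_p_one(self):
        r = compare_scenarios(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        assert r.t == 0.0 and r.p == 1.0

    def test_swap_flips_sign_only(self):
        a, b = np.array([1.0, 2.0, 4.0]), np.array([3.0, 5.0, 6.0])
        r1, r2 = compare_scenarios(a, b), compare_scenarios(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.df == pytest.approx(r2.df)


class TestBoxplotTable:
    def _result(self, pct, name="own season, own track"):
        sc = Scenario("A", "own", "own")
        df = pd.DataFrame(
            {"trip_id": [f"t{i}" for i in range(len(pct))], "duration_h": 10.0, "mean_speed_kmh": 20.0,
             "distance_km": 200.0, "pct_change": pct}
        )
        from petrelwind.scenarios import ScenarioResult

        return ScenarioResult(scenario=sc, per_trip=df, reference_duration_h=10.0)

    def test_quartiles_match_direct_computation(self):
        pct = [-10.0, -5.0, 0.0, 5.0, 30.0]
        tab = duration_boxplot_table([self._result(pct)])
        assert tab["median"].iloc[0] == 0.0
        assert tab["q1"].iloc[0] == np.percentile(pct, 25)
        assert tab["q3"].iloc[0] == np.percentile(pct, 75)

    def test_single_trip_degenerate_quartiles(self):
        tab = duration_boxplot_table([self._result([7.0])])
        assert tab["q1"].iloc[0] == tab["median"].iloc[0] == tab["q3"].iloc[0] == 7.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            duration_boxplot_table([])


def test_track_extent_drives_duration_change(world, truth, windfield):
    """Species differing only in trip extent: swapping tracks changes duration
    by the ratio of summed transit lengths; swapping season (flat wind and a
    shared surface) changes almost nothing."""
    from petrelwind.synthetic import TruthRecord, simulate_fleet
    from petrelwind.tracks import Trip
    from petrelwind.wind import annotate_fleet

    big_truth = TruthRecord(step_mean=(45.0, 15.0), step_sd=(9.0, 6.0))
    flat_world = WorldConfig(rng_seed=5, n_days=730)
    flat_wind = make_windfield(flat_world, mean_speed=8.0, seasonal_amplitude=0.0)

    def fleet_df(tr, species, seed):
        sims = simulate_fleet(world, tr, n_trips=4, n_steps=200, species=species, seed=seed)
        trips = []
        for s in sims:
            df = s.data[["timestamp", "lon", "lat"]].copy()
            df["imputed"] = False
            trips.append(Trip(s.data["trip_id"].iloc[0], s.data["bird_id"].iloc[0], df, 1.0, colony=world.colony))
        ann = annotate_fleet(trips, flat_wind)
        ann["state"] = 1
        return ann

    small = fleet_df(truth, "A", 61)
    big = fleet_df(big_truth, "B", 62)
    fit = fit_wind_gam(small, ar1=False)
    ref = float(observed_transit_durations(small).mean())

    own = run_scenario(Scenario("A", "own", "own"), small, flat_wind, fit, reference_duration_h=ref)
    other_track = run_scenario(Scenario("A", "other", "own"), big, flat_wind, fit, reference_duration_h=ref)
    other_season = run_scenario(
        Scenario("A", "own", "other", season_shift_months=2), small, flat_wind, fit, reference_duration_h=ref
    )
    assert other_track.per_trip["duration_h"].mean() > 1.2 * own.per_trip["duration_h"].mean()
    assert abs(other_season.mean_pct_change - own.mean_pct_change) < 1e-6
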