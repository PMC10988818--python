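import numpy as np
import pandas as pd
import pytest

from petrelwind.synthetic import TruthRecord, WorldConfig, make_windfield, simulate_fleet
from petrelwind.wind import annotate_fleet
from petrelwind.tracks import Trip


@pytest.fixture(scope="session")
def world() -> WorldConfig:
    return WorldConfig(rng_seed=1)


@pytest.fixture(scope="session")
def truth() -> TruthRecord:
    return TruthRecord()


@pytest.fixture(scope="session")
def windfield(world):
    return make_windfield(world, mean_speed=8.0, seasonal_amplitude=3.0)


@pytest.fixture(scope="session")
def fleet(world, truth):
    """Eight long 1-h trips from one species, fixed seed."""
    return simulate_fleet(world, truth, n_trips=8, n_steps=240, species="A", seed=11)


@pytest.fixture(scope="session")
def fleet_trips(fleet, world) -> list[Trip]:
    trips = []
    for sim in fleet:
        df = sim.data[["timestamp", "lon", "lat"]].copy()
        df["imputed"] = False
        trips.append(
            Trip(
                trip_id=sim.data["trip_id"].iloc[0],
                bird_id=sim.data["bird_id"].iloc[0],
                data=df,
                resolution_hours=1.0,
                colony=world.colony,
                trip_class="long",
            )
        )
    return trips


@pytest.fixture(scope="session")
def annotated(fleet_trips, windfield) -> pd.DataFrame:
    return annotate_fleet(fleet_trips, windfield)


@pytest.fixture(scope="session")
def true_states(fleet) -> dict[str, np.ndarray]:
    return {sim.data["trip_id"].iloc[0]: sim.states for sim in fleet}


@pytest.fixture(scope="session")
def clean_sims(world, truth):
    """Three long trips with the homing bias disabled: the pure switching
    process, the right target for estimator-recovery tests."""
    from petrelwind.synthetic import simulate_trip

    return [
        simulate_trip(world, truth, "2019-06-01", 500, bird_id=f"c{i}", trip_id=f"c{i}_t0", homing=False, seed=100 + i)
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def clean_annotated(clean_sims, world, windfield) -> pd.DataFrame:
    trips = []
    for sim in clean_sims:
        df = sim.data[["timestamp", "lon", "lat"]].copy()
        df["imputed"] = False
        trips.append(
            Trip(
                trip_id=sim.data["trip_id"].iloc[0],
                bird_id=sim.data["bird_id"].iloc[0],
                data=df,
                resolution_hours=1.0,
                colony=world.colony,
                trip_class="long",
            )
        )
    return annotate_fleet(trips, windfield)


@pytest.fixture(scope="session")
def clean_states(clean_sims):
    return {sim.data["trip_id"].iloc[0]: sim.states for sim in clean_sims}
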