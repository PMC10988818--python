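"""Two-state movement HMM: likelihood, decoding, parameter recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petrelwind.hmm import (
    HMMParams,
    MovementHMM,
    hmm_loglik,
    prepare_steps,
    state_probabilities,
    state_summaries,
    stationary_distribution,
    viterbi,
)


def _params(step_mean=(30.0, 10.0), step_sd=(8.0, 5.0), kappa=(8.0, 0.7), trans=((0.9, 0.1), (0.15, 0.85))):
    A = np.asarray(trans, float)
    return HMMParams(
        step_mean=step_mean,
        step_sd=step_sd,
        turn_kappa=kappa,
        turn_mean=(0.0, 0.0),
        transition=A,
        initial=stationary_distribution(A),
    )


def _emission_logpdf(p, s, step, turn):
    shape = (p.step_mean[s] / p.step_sd[s]) ** 2
    scale = p.step_sd[s] ** 2 / p.step_mean[s]
    ll = stats.gamma.logpdf(step, a=shape, scale=scale)
    if np.isfinite(turn):
        ll += stats.vonmises.logpdf(turn, kappa=p.turn_kappa[s], loc=p.turn_mean[s])
    return ll


def _brute_force_loglik(p, steps, turns):
    """Oracle: explicit sum over all 2^T state paths."""
    T = len(steps)
    total = -np.inf
    for path in itertools.product([0, 1], repeat=T):
        lp = np.log(p.initial[path[0]])
        for t in range(1, T):
            lp += np.log(p.transition[path[t - 1], path[t]])
        for t in range(T):
            lp += _emission_logpdf(p, path[t], steps[t], turns[t])
        total = np.logaddexp(total, lp)
    return total


def _seq(steps, turns, trip_id="t"):
    return {"trip_id": trip_id, "steps": np.asarray(steps, float), "turns": np.asarray(turns, float)}


class TestLogLikelihood:
    @pytest.mark.parametrize("T", [3, 5, 8])
    def test_forward_matches_exhaustive_enumeration(self, T):
        rng = np.random.default_rng(T)
        p = _params()
        steps = rng.gamma(4.0, 5.0, size=T) + 1.0
        turns = np.r_[np.nan, rng.vonmises(0, 1, size=T - 1)]
        seq = _seq(steps, turns)
        assert hmm_loglik(p, [seq]) == pytest.approx(_brute_force_loglik(p, steps, turns), abs=1e-9)

    def test_degenerate_single_state_equals_emission_sum(self):
        p = _params(step_mean=(20.0, 20.0), step_sd=(5.0, 5.0), kappa=(2.0, 2.0), trans=((1.0, 0.0), (0.0, 1.0)))
        p.initial = np.array([1.0, 0.0])
        steps = np.array([10.0, 25.0, 18.0])
        turns = np.array([np.nan, 0.3, -0.5])
        expected = sum(_emission_logpdf(p, 0, s, t) for s, t in zip(steps, turns))
        assert hmm_loglik(p, [_seq(steps, turns)]) == pytest.approx(expected, abs=1e-9)

    def test_independent_tracks_add(self):
        rng = np.random.default_rng(2)
        p = _params()
        seqs = [
            _seq(rng.gamma(4, 5, 6) + 1, np.r_[np.nan, rng.vonmises(0, 1, 5)], "a"),
            _seq(rng.gamma(4, 5, 4) + 1, np.r_[np.nan, rng.vonmises(0, 1, 3)], "b"),
        ]
        assert hmm_loglik(p, seqs) == pytest.approx(
            hmm_loglik(p, [seqs[0]]) + hmm_loglik(p, [seqs[1]]), abs=1e-9
        )


class TestViterbi:
    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(3)
        p = _params()
        steps = rng.gamma(4, 5, 3) + 1
        turns = np.r_[np.nan, rng.vonmises(0, 1, 2)]
        best, best_lp = None, -np.inf
        for path in itertools.product([0, 1], repeat=3):
            lp = np.log(p.initial[path[0]])
            for t in range(1, 3):
                lp += np.log(p.transition[path[t - 1], path[t]])
            for t in range(3):
                lp += _emission_logpdf(p, path[t], steps[t], turns[t])
            if lp > best_lp:
                best, best_lp = path, lp
        assert (viterbi(p, _seq(steps, turns)) == np.asarray(best) + 1).all()

    def test_uniform_everything_ties_to_transit(self):
        p = _params(step_mean=(10.0, 10.0), step_sd=(5.0, 5.0), kappa=(1.0, 1.0), trans=((0.5, 0.5), (0.5, 0.5)))
        path = viterbi(p, _seq([8.0, 12.0, 9.0], [np.nan, 0.1, -0.2]))
        assert (path == 1).all()

    def test_path_beats_random_paths(self):
        rng = np.random.default_rng(4)
        p = _params()
        steps = rng.gamma(4, 5, 12) + 1
        turns = np.r_[np.nan, rng.vonmises(0, 1, 11)]
        seq = _seq(steps, turns)

        def path_lp(path):
            lp = np.log(p.initial[path[0]])
            for t in range(1, len(path)):
                lp += np.log(p.transition[path[t - 1], path[t]])
            for t in range(len(path)):
                lp += _emission_logpdf(p, path[t], steps[t], turns[t])
            return lp

        vit_lp = path_lp(viterbi(p, seq) - 1)
        for _ in range(30):
            assert vit_lp >= path_lp(rng.integers(0, 2, size=len(steps))) - 1e-9

    def test_recovery_on_well_separated_states(self, world):
        from petrelwind.synthetic import TruthRecord, simulate_trip

        truth = TruthRecord(step_mean=(30.0, 5.0), step_sd=(6.0, 2.5))
        sim = simulate_trip(world, truth, "2019-06-01", 800, homing=False, seed=17)
        d = sim.data
        from petrelwind.geo import haversine_km, initial_bearing

        steps = haversine_km(d["lon"].values[:-1], d["lat"].values[:-1], d["lon"].values[1:], d["lat"].values[1:])
        brg = initial_bearing(d["lon"].values[:-1], d["lat"].values[:-1], d["lon"].values[1:], d["lat"].values[1:])
        turns = np.r_[np.nan, np.mod(np.diff(np.radians(brg)) + np.pi, 2 * np.pi) - np.pi]
        p = _params(step_mean=(30.0, 5.0), step_sd=(6.0, 2.5), kappa=(8.0, 0.7))
        decoded = viterbi(p, _seq(steps, turns))
        agreement = (decoded == sim.states[1:]).mean()
        assert agreement >= 0.95


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self, clean_annotated):
        return MovementHMM(clean_annotated).fit(n_restarts=3, seed=0)

    def test_parameter_recovery_within_10_percent(self, fitted):
        p = fitted.params
        assert abs(p.step_mean[0] - 30.0) / 30.0 < 0.10
        assert abs(p.step_mean[1] - 10.0) / 10.0 < 0.10

    def test_viterbi_agreement_with_truth(self, fitted, clean_states):
        agree = total = 0
        for trip_id, path in fitted.viterbi_states.items():
            truth = clean_states[trip_id][1:]  # states per step (positions minus first)
            agree += (path == truth).sum()
            total += len(path)
        assert agree / total >= 0.90

    def test_tighter_tolerance_never_lowers_loglik(self, clean_annotated):
        model = MovementHMM(clean_annotated)
        loose = model.fit(n_restarts=1, tol=1e-4, seed=0)
        tight = model.fit(n_restarts=1, tol=1e-10, seed=0)
        assert tight.log_likelihood >= loose.log_likelihood - 1e-6

    def test_state_probabilities_sum_to_one(self, fitted):
        for probs in fitted.state_probabilities.values():
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_data_warns(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "trip_id": "t",
                "timestamp": pd.date_range("2019-06-01", periods=300, freq="1h"),
                "step_length_km": rng.gamma(16, 1.25, 300),
                "bearing_deg": np.cumsum(rng.vonmises(0, 4, 300)) % 360,
            }
        )
        with pytest.warns(UserWarning, match="single state"):
            MovementHMM(df).fit(n_restarts=2, seed=1)

    def test_summary_mentions_states(self, fitted):
        text = fitted.summary()
        assert "transit" in text and "search" in text


class TestStateSummaries:
    def test_hand_built_trip(self):
        p = _params(step_mean=(30.0, 5.0), step_sd=(3.0, 1.0))
        df = pd.DataFrame(
            {
                "trip_id": "t",
                "timestamp": pd.date_range("2019-06-01", periods=4, freq="1h"),
                "step_length_km": [30.0, 31.0, 5.0, 5.5],
                "bearing_deg": [10.0, 12.0, 100.0, 250.0],
                "ground_speed_kmh": [30.0, 31.0, 5.0, 5.5],
                "resolution_hours": 1.0,
            }
        )

        class FakeModel:
            sequences = prepare_steps(df)

        from petrelwind.hmm import MovementHMMResults

        res = MovementHMMResults(model=FakeModel(), params=p, log_likelihood=0.0, restart_index=0, n_iterations=0, tol=0)
        tab = state_summaries(res, df)
        transit = tab[tab["section"] == "transit"].iloc[0]
        assert transit["ground_speed_kmh_mean"] == pytest.approx(30.5)
        all_row = tab[tab["section"] == "all"].iloc[0]
        assert all_row["search_share_pct_mean"] == pytest.approx(50.0)

    def test_all_transit_zero_search_share(self):
        p = _params(step_mean=(30.0, 1.0), step_sd=(3.0, 0.5))
        df = pd.DataFrame(
            {
                "trip_id": "t",
                "timestamp": pd.date_range("2019-06-01", periods=5, freq="1h"),
                "step_length_km": [29.0, 30.0, 31.0, 30.0, 29.5],
                "bearing_deg": [10.0, 10.5, 11.0, 11.5, 12.0],
                "ground_speed_kmh": [29.0, 30.0, 31.0, 30.0, 29.5],
                "resolution_hours": 1.0,
            }
        )

        class FakeModel:
            sequences = prepare_steps(df)

        from petrelwind.hmm import MovementHMMResults

        res = MovementHMMResults(model=FakeModel(), params=p, log_likelihood=0.0, restart_index=0, n_iterations=0, tol=0)
        tab = state_summaries(res, df)
        assert tab[tab["section"] == "all"]["search_share_pct_mean"].iloc[0] == 0.0


def test_transit_fraction_tracks_generator_occupancy(world):
    """Decoded transit share rises with the generator's transit occupancy."""
    from petrelwind.geo import haversine_km, initial_bearing
    from petrelwind.synthetic import TruthRecord, simulate_trip

    shares = []
    for p12, p21 in ((0.3, 0.05), (0.1, 0.1), (0.05, 0.3)):
        truth = TruthRecord(transition=((1 - p12, p12), (p21, 1 - p21)))
        sim = simulate_trip(world, truth, "2019-06-01", 600, homing=False, seed=29)
        d = sim.data
        steps = haversine_km(d["lon"].values[:-1], d["lat"].values[:-1], d["lon"].values[1:], d["lat"].values[1:])
        brg = initial_bearing(d["lon"].values[:-1], d["lat"].values[:-1], d["lon"].values[1:], d["lat"].values[1:])
        turns = np.r_[np.nan, np.mod(np.diff(np.radians(brg)) + np.pi, 2 * np.pi) - np.pi]
        p = _params(trans=((1 - p12, p12), (p21, 1 - p21)))
        shares.append((viterbi(p, _seq(steps, turns)) == 1).mean())
    assert shares[0] < shares[1] < shares[2]
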