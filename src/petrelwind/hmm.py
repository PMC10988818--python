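"""Two-state movement HMM: gamma step lengths, von Mises turning angles.

The model classifies movement steps into "transit" (fast, directionally
persistent) and "search" (slow, tortuous) states.  Emissions are a gamma
density on step length and a von Mises density on turning angle (centred
at zero by default); the hidden chain is a 2-state discrete-time Markov
chain whose initial distribution is taken as the stationary distribution
of the transition matrix.  The likelihood is the exact scaled forward
recursion; fitting is direct numerical maximization from several
perturbed starting points, and decoding uses the Viterbi algorithm.

State 1 is always the larger-mean-step state (transit); label switching
is resolved by reordering after every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

_EPS = 1e-300


class EstimationError(RuntimeError):
    """No restart of the likelihood maximization converged."""


@dataclass
class HMMParams:
    """Parameters of the 2-state step/turn HMM (state order: transit, search)."""

    step_mean: np.ndarray  # km
    step_sd: np.ndarray
    turn_kappa: np.ndarray
    turn_mean: np.ndarray  # radians
    transition: np.ndarray  # rows sum to 1
    initial: np.ndarray

    def __post_init__(self) -> None:
        for name in ("step_mean", "step_sd", "turn_kappa", "turn_mean", "transition", "initial"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma parameters must be positive")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_scale(self) -> np.ndarray:
        return self.step_sd**2 / self.step_mean

    def ordered(self) -> "HMMParams":
        """Return a copy with states sorted so state 1 has the larger step mean."""
        if self.step_mean[0] >= self.step_mean[1]:
            return self
        o = [1, 0]
        return HMMParams(
            step_mean=self.step_mean[o],
            step_sd=self.step_sd[o],
            turn_kappa=self.turn_kappa[o],
            turn_mean=self.turn_mean[o],
            transition=self.transition[np.ix_(o, o)],
            initial=self.initial[o],
        )


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    a, b = transition[0, 1], transition[1, 0]
    if a + b <= 0:
        return np.array([0.5, 0.5])
    return np.array([b / (a + b), a / (a + b)])


def prepare_steps(annotated: pd.DataFrame, min_step_km: float | None = None) -> list[dict]:
    """Group an annotated-step table into per-trip step/turn arrays.

    Turning angles are heading changes between consecutive steps, wrapped
    to (-π, π]; the first step of each trip has no turning angle.  Zero
    (or sub-threshold) step lengths are replaced by half the smallest
    positive step so they stay inside the gamma support.
    """
    seqs = []
    positive = annotated.loc[annotated["step_length_km"] > 0, "step_length_km"]
    floor = (min_step_km if min_step_km is not None else float(positive.min()) / 2.0) if len(positive) else 1e-3
    for trip_id, g in annotated.groupby("trip_id", sort=False):
        g = g.sort_values("timestamp")
        steps = g["step_length_km"].to_numpy(dtype=float)
        n_floored = int((steps < floor).sum())
        steps = np.maximum(steps, floor)
        bearing = np.radians(g["bearing_deg"].to_numpy(dtype=float))
        turns = np.full(steps.shape, np.nan)
        db = np.diff(bearing)
        turns[1:] = np.mod(db + np.pi, 2 * np.pi) - np.pi
        seqs.append({"trip_id": trip_id, "steps": steps, "turns": turns, "n_floored": n_floored})
    return seqs


def _log_emissions(params: HMMParams, steps: np.ndarray, turns: np.ndarray) -> np.ndarray:
    T = steps.size
    logB = np.zeros((T, 2))
    for s in range(2):
        logB[:, s] = stats.gamma.logpdf(steps, a=params.gamma_shape[s], scale=params.gamma_scale[s])
        ok = np.isfinite(turns)
        logB[ok, s] += stats.vonmises.logpdf(turns[ok], kappa=params.turn_kappa[s], loc=params.turn_mean[s])
    return logB


def _forward(params: HMMParams, logB: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward pass: returns (loglik, alpha_hat, log scale factors)."""
    T = logB.shape[0]
    A = params.transition
    alpha = np.empty((T, 2))
    logc = np.empty(T)
    m = logB[0].max()
    a = params.initial * np.exp(logB[0] - m)
    c = a.sum()
    alpha[0] = a / max(c, _EPS)
    logc[0] = np.log(max(c, _EPS)) + m
    for t in range(1, T):
        m = logB[t].max()
        a = (alpha[t - 1] @ A) * np.exp(logB[t] - m)
        c = a.sum()
        alpha[t] = a / max(c, _EPS)
        logc[t] = np.log(max(c, _EPS)) + m
    return float(logc.sum()), alpha, logc


def hmm_loglik(params: HMMParams, sequences: list[dict]) -> float:
    """Exact log-likelihood of independent trips under the 2-state HMM."""
    total = 0.0
    for seq in sequences:
        logB = _log_emissions(params, seq["steps"], seq["turns"])
        ll, _, _ = _forward(params, logB)
        total += ll
    return total


def viterbi(params: HMMParams, sequence: dict) -> np.ndarray:
    """Globally most probable state path (1 = transit, 2 = search).

    Log-space dynamic programming; ties break to the lower-numbered
    state (transit).
    """
    logB = _log_emissions(params, sequence["steps"], sequence["turns"])
    T = logB.shape[0]
    logA = np.log(np.maximum(params.transition, _EPS))
    logd = np.log(np.maximum(params.initial, _EPS)) + logB[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        cand = logd[:, None] + logA  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)
        logd = cand[back[t], [0, 1]] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(logd))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path + 1


def state_probabilities(params: HMMParams, sequence: dict) -> np.ndarray:
    """Per-point posterior state probabilities (forward-backward)."""
    logB = _log_emissions(params, sequence["steps"], sequence["turns"])
    T = logB.shape[0]
    _, alpha, logc = _forward(params, logB)
    A = params.transition
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        m = logB[t + 1].max()
        b = A @ (np.exp(logB[t + 1] - m) * beta[t + 1])
        scale = np.exp(logc[t + 1] - m)
        beta[t] = b / max(scale, _EPS)
    gamma = alpha * beta
    return gamma / gamma.sum(axis=1, keepdims=True)


def _gamma_overlap(params: HMMParams, n_grid: int = 2000) -> float:
    """Overlap coefficient of the two fitted step-length densities (0..1)."""
    hi = float(np.max(params.step_mean + 6 * params.step_sd))
    x = np.linspace(1e-6, hi, n_grid)
    f = [stats.gamma.pdf(x, a=params.gamma_shape[s], scale=params.gamma_scale[s]) for s in range(2)]
    return float(np.trapezoid(np.minimum(f[0], f[1]), x))


# ---------------------------------------------------------------------------
# Model / Results


class MovementHMM:
    """2-state step/turn HMM for a set of trips at one temporal resolution.

    Parameters
    ----------
    annotated : DataFrame
        Per-step table with ``trip_id``, ``timestamp``, ``step_length_km``
        and ``bearing_deg`` columns (the output of wind annotation, or any
        table with those columns).
    estimate_turn_mean : bool
        Estimate the von Mises centres instead of fixing them at zero.
    """

    def __init__(self, annotated: pd.DataFrame, estimate_turn_mean: bool = False):
        self.sequences = prepare_steps(annotated)
        if not self.sequences:
            raise ValueError("no trips in input")
        self.estimate_turn_mean = estimate_turn_mean
        self._steps_all = np.concatenate([s["steps"] for s in self.sequences])

    # -- parameter packing -------------------------------------------------
    def _pack(self, p: HMMParams) -> np.ndarray:
        theta = [
            *np.log(p.step_mean),
            *np.log(p.step_sd),
            *np.log(np.maximum(p.turn_kappa, 1e-6)),
            float(np.log(p.transition[0, 1] / (1 - p.transition[0, 1]))),
            float(np.log(p.transition[1, 0] / (1 - p.transition[1, 0]))),
        ]
        if self.estimate_turn_mean:
            theta.extend(p.turn_mean)
        return np.asarray(theta, dtype=float)

    def _unpack(self, theta: np.ndarray) -> HMMParams:
        m = np.exp(theta[0:2])
        s = np.exp(theta[2:4])
        k = np.exp(theta[4:6])
        a12 = 1.0 / (1.0 + np.exp(-theta[6]))
        a21 = 1.0 / (1.0 + np.exp(-theta[7]))
        mu = np.asarray(theta[8:10]) if self.estimate_turn_mean else np.zeros(2)
        A = np.array([[1 - a12, a12], [a21, 1 - a21]])
        return HMMParams(
            step_mean=m, step_sd=s, turn_kappa=k, turn_mean=mu, transition=A, initial=stationary_distribution(A)
        )

    def _start_values(self, rng: np.random.Generator, perturb: bool) -> HMMParams:
        q = np.quantile(self._steps_all, [0.25, 0.75])
        mean = np.array([q[1], q[0]])
        if perturb:
            mean = mean * rng.uniform(0.6, 1.6, size=2)
        sd = np.maximum(mean * 0.5, 1e-3)
        kappa = np.array([4.0, 0.5]) * (rng.uniform(0.5, 2.0, size=2) if perturb else 1.0)
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        return HMMParams(
            step_mean=np.maximum(mean, 1e-3),
            step_sd=sd,
            turn_kappa=kappa,
            turn_mean=np.zeros(2),
            transition=A,
            initial=stationary_distribution(A),
        )

    def loglik(self, params: HMMParams) -> float:
        return hmm_loglik(params, self.sequences)

    def fit(self, n_restarts: int = 10, tol: float = 1e-8, seed: int = 0, maxiter: int = 500) -> "MovementHMMResults":
        """Maximize the forward log-likelihood from perturbed starts.

        The best converged restart wins; states are reordered so transit
        (state 1) is the larger-step state.  Raises
        :class:`EstimationError` if every restart fails.
        """
        rng = np.random.default_rng(seed)
        best = None
        history = []

        def nll(theta):
            try:
                return -self.loglik(self._unpack(theta))
            except (ValueError, FloatingPointError):
                return 1e12

        for r in range(n_restarts):
            start = self._start_values(rng, perturb=r > 0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    nll,
                    self._pack(start),
                    method="L-BFGS-B",
                    options={"ftol": tol, "gtol": 1e-8, "maxiter": maxiter},
                )
            history.append({"restart": r, "loglik": -res.fun, "converged": bool(res.success), "nit": res.nit})
            if res.fun < 1e11 and (best is None or res.fun < best[0]):
                best = (res.fun, res.x, r, res)
        if best is None:
            raise EstimationError(f"all {n_restarts} restarts failed: {history}")
        params = self._unpack(best[1]).ordered()
        paths = np.concatenate([viterbi(params, s) for s in self.sequences])
        occupancy = float((paths == 1).mean())
        if _gamma_overlap(params) > 0.5 or min(occupancy, 1 - occupancy) < 0.02:
            warnings.warn(
                "state emission distributions overlap strongly or one state is (nearly) "
                "unoccupied; data may hold a single state",
                stacklevel=2,
            )
        return MovementHMMResults(
            model=self,
            params=params,
            log_likelihood=-best[0],
            restart_index=best[2],
            n_iterations=int(best[3].nit),
            tol=tol,
            history=history,
        )


@dataclass
class MovementHMMResults:
    """Fitted 2-state movement HMM with decoding helpers."""

    model: MovementHMM
    params: HMMParams
    log_likelihood: float
    restart_index: int
    n_iterations: int
    tol: float
    history: list = field(default_factory=list)

    @property
    def viterbi_states(self) -> dict[str, np.ndarray]:
        """Most likely state path per trip (1 = transit, 2 = search)."""
        return {s["trip_id"]: viterbi(self.params, s) for s in self.model.sequences}

    @property
    def state_probabilities(self) -> dict[str, np.ndarray]:
        return {s["trip_id"]: state_probabilities(self.params, s) for s in self.model.sequences}

    def decode(self, annotated: pd.DataFrame) -> pd.DataFrame:
        """Return the annotated table with a ``state`` column appended."""
        out = []
        for trip_id, g in annotated.groupby("trip_id", sort=False):
            g = g.sort_values("timestamp").copy()
            seq = prepare_steps(g)[0]
            g["state"] = viterbi(self.params, seq)
            out.append(g)
        return pd.concat(out, ignore_index=True)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-state movement HMM (gamma step, von Mises turn)",
            f"  log-likelihood: {self.log_likelihood:.3f}   "
            f"(restart {self.restart_index}, {self.n_iterations} iterations, ftol {self.tol:g})",
            f"  {'state':<10}{'step mean km':>14}{'step sd km':>12}{'turn kappa':>12}",
            f"  {'transit':<10}{p.step_mean[0]:>14.3f}{p.step_sd[0]:>12.3f}{p.turn_kappa[0]:>12.3f}",
            f"  {'search':<10}{p.step_mean[1]:>14.3f}{p.step_sd[1]:>12.3f}{p.turn_kappa[1]:>12.3f}",
            f"  transition matrix: [[{p.transition[0, 0]:.3f}, {p.transition[0, 1]:.3f}], "
            f"[{p.transition[1, 0]:.3f}, {p.transition[1, 1]:.3f}]]",
            f"  stationary transit share: {p.initial[0]:.3f}",
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        p = self.params
        return {
            "step_mean_km": p.step_mean.tolist(),
            "step_sd_km": p.step_sd.tolist(),
            "turn_kappa": p.turn_kappa.tolist(),
            "turn_mean_rad": p.turn_mean.tolist(),
            "transition": p.transition.tolist(),
            "initial": p.initial.tolist(),
            "log_likelihood": self.log_likelihood,
            "restart_index": self.restart_index,
            "n_iterations": self.n_iterations,
        }


def state_summaries(results: MovementHMMResults, annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-state summary with the trip as sampling unit.

    Means of ground speed, wind speed, TWC and Δangle are computed per
    trip and state, then averaged across trips (mean and sd across
    trips); the search-state time share is reported per trip the same
    way.  Rows: transit, search, all.
    """
    decoded = results.decode(annotated)
    per_trip = []
    for trip_id, g in decoded.groupby("trip_id"):
        row = {"trip_id": trip_id, "search_share_pct": 100.0 * float((g["state"] == 2).mean())}
        for label, sub in (("transit", g[g["state"] == 1]), ("search", g[g["state"] == 2]), ("all", g)):
            for col in ("ground_speed_kmh", "wind_speed_kmh", "twc_kmh", "delta_angle_deg"):
                if col in g.columns:
                    row[f"{label}_{col}"] = float(sub[col].mean()) if len(sub) else np.nan
        per_trip.append(row)
    pt = pd.DataFrame(per_trip)
    rows = []
    for label in ("transit", "search", "all"):
        row = {"section": label}
        for col in ("ground_speed_kmh", "wind_speed_kmh", "twc_kmh", "delta_angle_deg"):
            key = f"{label}_{col}"
            if key in pt.columns:
                row[f"{col}_mean"] = float(pt[key].mean())
                row[f"{col}_sd"] = float(pt[key].std())
        if label == "all":
            row["search_share_pct_mean"] = float(pt["search_share_pct"].mean())
            row["search_share_pct_sd"] = float(pt["search_share_pct"].std())
        rows.append(row)
    return pd.DataFrame(rows)
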