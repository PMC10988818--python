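"""Config-driven end-to-end pipeline over the synthetic world.

Runs the full analysis chain — generate → preprocess → annotate → hmm →
ud / habitat / windgam → scenarios → ancillary — writing every stage's
outputs (CSV/JSON/NetCDF) into a run directory.  Stages are idempotent:
a stage whose outputs already exist is skipped unless forced, so a
downstream stage can be rerun against cached upstream results.  A
manifest records the configuration, seeds and stage timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from petrelwind import ancillary as anc
from petrelwind import synthetic
from petrelwind.habitat import BoostedHabitatModel, draw_pseudo_absences, habitat_covariates
from petrelwind.hmm import MovementHMM, state_summaries
from petrelwind.scenarios import (
    Scenario,
    compare_scenarios,
    duration_boxplot_table,
    incubation_window_shift,
    observed_transit_durations,
    run_scenario,
)
from petrelwind.spaceuse import make_grid, synchronize_phenology, yearly_overlap_table
from petrelwind.synthetic import TruthRecord, WorldConfig
from petrelwind.tracks import Trip, classify_trips, filter_long, trip_summary_table
from petrelwind.wind import annotate_fleet
from petrelwind.windgam import WindSpeedGAM

log = logging.getLogger("petrelwind.pipeline")

STAGES = ("simulate", "preprocess", "annotate", "hmm", "ud", "habitat", "windgam", "scenarios", "ancillary")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialized next to the outputs."""

    seed: int = 1
    outdir: str = "petrelwind_run"
    resolution_hours: int = 1
    wind_convention: str = "to"  # reported wind-direction convention
    # world
    world: dict = field(default_factory=dict)
    mean_wind_speed: float = 8.0
    seasonal_amplitude: float = 3.0
    # fleets: species A breeds earlier, smaller trips; B later, larger trips
    n_trips: int = 8
    n_steps: int = 240
    species_a_start: str = "2019-06-19"
    species_b_start: str = "2019-08-28"
    truth_a: dict = field(default_factory=dict)
    truth_b: dict = field(default_factory=lambda: {"step_mean": (36.0, 12.0), "step_sd": (9.0, 6.0)})
    n_short: int = 2
    # GLS
    n_gls_birds: int = 5
    phenology_lag_months: int = 2
    hmm_restarts: int = 4
    # UD
    ud_h_deg: float = 2.25
    ud_grid_res: float = 0.25
    ud_levels: tuple = (0.5, 0.75)
    # habitat BRT (demo-scale hyperparameters; the model defaults are 0.005/3/0.75)
    brt_learning_rate: float = 0.05
    brt_tree_complexity: int = 3
    brt_bag_fraction: float = 0.75
    brt_n_folds: int = 5
    brt_max_trees: int = 400
    # wind GAM
    gam_n_basis: int = 8
    gam_use_interaction: bool = True
    # scenarios: incubation date-window mode by default
    incubation_a: str = "2019-06-19"
    incubation_b: str = "2019-08-28"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    pass


def _stage_done(outdir: Path, stage: str) -> bool:
    return (outdir / f".{stage}.done").exists()


def _mark_done(outdir: Path, stage: str, seconds: float) -> None:
    (outdir / f".{stage}.done").write_text(json.dumps({"seconds": seconds}))


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES, force: bool = False) -> Path:
    """Execute the pipeline stages in order; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {"seed": config.seed, "stages": {}}
    if (outdir / "manifest.json").exists():
        manifest["stages"] = json.loads((outdir / "manifest.json").read_text()).get("stages", {})
    for stage in STAGES:
        if stage not in stages:
            continue
        if _stage_done(outdir, stage) and not force:
            log.info("stage %s: cached, skipping", stage)
            continue
        fn = globals()[f"_stage_{stage}"]
        t0 = time.perf_counter()
        log.info("stage %s: running", stage)
        try:
            fn(config, outdir)
        except FileNotFoundError as exc:
            raise StageError(f"stage '{stage}' missing input: {exc}") from exc
        dt = time.perf_counter() - t0
        _mark_done(outdir, stage, dt)
        manifest["stages"][stage] = round(dt, 2)
        log.info("stage %s: done in %.1f s", stage, dt)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _world(config: PipelineConfig) -> WorldConfig:
    return WorldConfig(rng_seed=config.seed, **config.world)


def _truths(config: PipelineConfig) -> dict[str, TruthRecord]:
    return {"A": TruthRecord(**config.truth_a), "B": TruthRecord(**config.truth_b)}


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    world = _world(config)
    wind = synthetic.make_windfield(world, config.mean_wind_speed, config.seasonal_amplitude)
    synthetic.write_windfield(wind, outdir / "wind.nc")
    truths = _truths(config)
    states = {}
    for sp, start in (("A", config.species_a_start), ("B", config.species_b_start)):
        fleet = synthetic.simulate_fleet(
            world,
            truths[sp],
            n_trips=config.n_trips,
            n_steps=config.n_steps,
            resolution_hours=config.resolution_hours,
            start_time=start,
            species=sp,
            n_short=config.n_short,
            seed=config.seed + (0 if sp == "A" else 500),
        )
        synthetic.tracks_to_csv(fleet, outdir / f"tracks_{sp}.csv")
        states[sp] = {t.data["trip_id"].iloc[0]: t.states.tolist() for t in fleet}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "hmm": {sp: json.loads(t.to_json()) for sp, t in truths.items()},
                "true_states": states,
            },
            fh,
        )
    for sp, lag in (("A", 0), ("B", config.phenology_lag_months)):
        locs, imm = synthetic.simulate_gls_year(
            world,
            n_birds=config.n_gls_birds,
            species=sp,
            phenology_lag_months=lag,
            seed=config.seed + (7 if sp == "A" else 507),
        )
        locs.to_csv(outdir / f"gls_locations_{sp}.csv", index=False)
        imm.to_csv(outdir / f"immersion_{sp}.csv", index=False)
    synthetic.simulate_isotopes(25, seed=config.seed).to_csv(outdir / "isotopes.csv", index=False)


def _load_trips(config: PipelineConfig, outdir: Path, species: str) -> list[Trip]:
    raw = pd.read_csv(outdir / f"tracks_{species}.csv", parse_dates=["timestamp"])
    world = _world(config)
    trips = []
    for trip_id, g in raw.groupby("trip_id"):
        g = g.sort_values("timestamp").reset_index(drop=True)
        df = g[["timestamp", "lon", "lat"]].copy()
        df["imputed"] = False
        trips.append(
            Trip(
                trip_id=trip_id,
                bird_id=g["bird_id"].iloc[0],
                data=df,
                resolution_hours=float(config.resolution_hours),
                colony=world.colony,
            )
        )
    return trips


def _stage_preprocess(config: PipelineConfig, outdir: Path) -> None:
    for sp in ("A", "B"):
        trips = _load_trips(config, outdir, sp)
        classify_trips(trips, seed=config.seed)
        long_trips = filter_long(trips)
        trip_summary_table(trips).to_csv(outdir / f"trip_summary_{sp}.csv", index=False)
        pd.concat([t.data.assign(trip_id=t.trip_id, bird_id=t.bird_id) for t in long_trips]).to_csv(
            outdir / f"long_tracks_{sp}.csv", index=False
        )


def _stage_annotate(config: PipelineConfig, outdir: Path) -> None:
    wind = synthetic.read_windfield(outdir / "wind.nc")
    for sp in ("A", "B"):
        trips = _load_trips(config, outdir, sp)
        classify_trips(trips, seed=config.seed)
        long_trips = filter_long(trips)
        ann = annotate_fleet(long_trips, wind)
        if config.wind_convention == "from":
            ann["wind_from_direction_deg"] = (ann["wind_to_direction_deg"] + 180.0) % 360.0
        ann.to_csv(outdir / f"annotated_{sp}.csv", index=False)


def _stage_hmm(config: PipelineConfig, outdir: Path) -> None:
    for sp in ("A", "B"):
        ann = pd.read_csv(outdir / f"annotated_{sp}.csv", parse_dates=["timestamp"])
        fit = MovementHMM(ann).fit(n_restarts=config.hmm_restarts, seed=config.seed)
        decoded = fit.decode(ann)
        decoded.to_csv(outdir / f"decoded_{sp}.csv", index=False)
        with open(outdir / f"hmm_fit_{sp}.json", "w") as fh:
            json.dump(fit.to_json_dict(), fh, indent=2)
        state_summaries(fit, ann).to_csv(outdir / f"state_summary_{sp}.csv", index=False)


def _stage_ud(config: PipelineConfig, outdir: Path) -> None:
    locs = {sp: pd.read_csv(outdir / f"gls_locations_{sp}.csv", parse_dates=["date"]) for sp in ("A", "B")}
    world = _world(config)
    grid = make_grid(world.lon_min, world.lon_max, world.lat_min, world.lat_max, config.ud_grid_res)
    obs = yearly_overlap_table(
        locs["A"], locs["B"], grid, h_deg=config.ud_h_deg, levels=tuple(config.ud_levels), scenario="observed"
    )
    sync = yearly_overlap_table(
        synchronize_phenology(locs["A"], config.phenology_lag_months),
        locs["B"],
        grid,
        h_deg=config.ud_h_deg,
        levels=tuple(config.ud_levels),
        scenario="synchronized",
    )
    pd.concat([obs, sync]).to_csv(outdir / "ud_overlap.csv", index=False)


def _stage_habitat(config: PipelineConfig, outdir: Path) -> None:
    world = _world(config)
    wind = synthetic.read_windfield(outdir / "wind.nc")
    boxes = []
    for sp in ("A", "B"):
        d = pd.read_csv(outdir / f"decoded_{sp}.csv")
        boxes.append((d["lon"].min(), d["lon"].max(), d["lat"].min(), d["lat"].max()))
    bounds = (
        min(b[0] for b in boxes),
        max(b[1] for b in boxes),
        min(b[2] for b in boxes),
        max(b[3] for b in boxes),
    )
    covariates = ["sst", "dist_colony_km", "dist_seamount_km", "wind_speed", "depth_m"]
    for sp in ("A", "B"):
        decoded = pd.read_csv(outdir / f"decoded_{sp}.csv")
        pres = decoded.loc[decoded["state"] == 2, ["lon", "lat"]].copy()
        pres["presence"] = 1
        absn = draw_pseudo_absences(pres, world.colony, world, bounds=bounds, seed=config.seed)
        data = habitat_covariates(pd.concat([pres, absn], ignore_index=True), world, wind)
        model = BoostedHabitatModel(data, covariates)
        fit = model.fit(
            learning_rate=config.brt_learning_rate,
            tree_complexity=config.brt_tree_complexity,
            bag_fraction=config.brt_bag_fraction,
            n_folds=config.brt_n_folds,
            max_trees=config.brt_max_trees,
            seed=config.seed,
        )
        fit.variable_importance().rename("importance_pct").to_csv(outdir / f"brt_importance_{sp}.csv")
        fit.cv_metrics.to_csv(outdir / f"brt_cv_{sp}.csv", index=False)
        pd.concat(
            [fit.partial_dependence(c).rename(columns={c: "value"}).assign(covariate=c) for c in covariates]
        ).to_csv(outdir / f"brt_partial_dependence_{sp}.csv", index=False)
        with open(outdir / f"brt_fit_{sp}.json", "w") as fh:
            json.dump(
                {
                    "n_trees": fit.n_trees,
                    "cv_auc_mean": float(fit.cv_metrics["auc"].mean()),
                    "importance_pct": fit.variable_importance().to_dict(),
                },
                fh,
                indent=2,
            )


def _stage_windgam(config: PipelineConfig, outdir: Path) -> None:
    for sp in ("A", "B"):
        decoded = pd.read_csv(outdir / f"decoded_{sp}.csv", parse_dates=["timestamp"])
        transit = decoded[decoded["state"] == 1]
        fit = WindSpeedGAM(
            transit, n_basis=config.gam_n_basis, use_interaction=config.gam_use_interaction
        ).fit()
        fit.surface_heatmap().to_csv(outdir / f"gam_surface_{sp}.csv")
        with open(outdir / f"gam_fit_{sp}.json", "w") as fh:
            json.dump(
                {
                    "coef": fit.coef.tolist(),
                    "lambdas": fit.lambdas.tolist(),
                    "rho": fit.rho,
                    "deviance": fit.deviance,
                    "edf": fit.edf,
                },
                fh,
                indent=2,
            )
        (outdir / f"gam_summary_{sp}.txt").write_text(fit.summary() + "\n")


def _stage_scenarios(config: PipelineConfig, outdir: Path) -> None:
    wind = synthetic.read_windfield(outdir / "wind.nc")
    decoded = {
        sp: pd.read_csv(outdir / f"decoded_{sp}.csv", parse_dates=["timestamp"]) for sp in ("A", "B")
    }
    fits = {}
    for sp in ("A", "B"):
        transit = decoded[sp][decoded[sp]["state"] == 1]
        fits[sp] = WindSpeedGAM(
            transit, n_basis=config.gam_n_basis, use_interaction=config.gam_use_interaction
        ).fit()
    shifts = {
        "A": incubation_window_shift(config.incubation_a, config.incubation_b),
        "B": incubation_window_shift(config.incubation_b, config.incubation_a),
    }
    results = {}
    rows = []
    for focal, other in (("A", "B"), ("B", "A")):
        ref = float(observed_transit_durations(decoded[focal]).mean())
        cells = {
            ("own", "own"): Scenario(focal, "own", "own"),
            ("own", "other"): Scenario(focal, "own", "other", season_shift_days=shifts[focal]),
            ("other", "own"): Scenario(focal, "other", "own"),
            ("other", "other"): Scenario(focal, "other", "other", season_shift_days=shifts[focal]),
        }
        for (track, season), sc in cells.items():
            tracks = decoded[focal if track == "own" else other]
            res = run_scenario(sc, tracks, wind, fits[focal], reference_duration_h=ref)
            results[(focal, track, season)] = res
            res.per_trip.assign(focal=focal, track=track, season=season).to_csv(
                outdir / f"scenario_{focal}_{track}track_{season}season.csv", index=False
            )
        rows.append(
            {
                "focal": focal,
                "own_vs_other_track": str(
                    compare_scenarios(results[(focal, "own", "own")], results[(focal, "other", "own")])
                ),
                "own_vs_other_season": str(
                    compare_scenarios(results[(focal, "own", "own")], results[(focal, "own", "other")])
                ),
            }
        )
    duration_boxplot_table(list(results.values())).to_csv(outdir / "scenario_boxplot.csv", index=False)
    with open(outdir / "scenario_ttests.json", "w") as fh:
        json.dump(rows, fh, indent=2)


def _stage_ancillary(config: PipelineConfig, outdir: Path) -> None:
    out = {}
    for sp in ("A", "B"):
        imm = pd.read_csv(outdir / f"immersion_{sp}.csv", parse_dates=["date"])
        _, means = anc.daily_activity(imm)
        out[f"activity_{sp}"] = means
        out[f"moon_{sp}"] = anc.activity_moon_correlation(imm)
    iso = pd.read_csv(outdir / "isotopes.csv")
    anc.isotope_anova(iso).to_csv(outdir / "isotope_anova.csv", index=False)
    out["allometry"] = {
        "wing_loading_small_g_cm2": anc.wing_loading(200, 460, 2),
        "wing_loading_large_g_cm2": anc.wing_loading(300, 584, 2),
        "isometric_mass_increase_pct_10pct_span": round(anc.isometric_mass_increase(1.10)),
    }
    with open(outdir / "ancillary.json", "w") as fh:
        json.dump(out, fh, indent=2)
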