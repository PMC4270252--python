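"""Orchestration: study configuration, seeds, summaries, end-to-end runner.

``run_synthetic_study`` wires the whole pipeline together: it draws a
synthetic population, simulates stimulus trials and behavior for the three
tasks, runs every analysis stage, and emits a recovery report comparing the
recovered population parameters with their generating values.

Posterior summary conventions follow the reporting style used throughout
the package: mean plus 50% and 95% percentile intervals, split R-hat over
four chains with the R-hat < 1.05 convergence criterion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bisection_model, kinematics, lma_model, recall_model
from . import synthetic_participant as sp
from ._sampling import PosteriorSummary, check_convergence, summarize_draws
from .kinematics import DisplayGeometry, MotionParams

logger = logging.getLogger("wolfpack")

# pivot-shift schedules used in the second block, by stimulus and phase
PIVOT_SCHEDULES = {
    "circle_early": (-0.15, -0.05, 0.05, 0.1, 0.15, 0.2),
    "circle_late": (0.05, 0.1, 0.15, 0.2, 0.25, 0.3),
    "dart_early": (-0.4, -0.2),
    "dart_late": (0.4, 0.2),
    "dart_full": (-0.4, -0.2, 0.2, 0.4),
}


def summarize(draws: np.ndarray, name: str = "parameter") -> PosteriorSummary:
    """Posterior summary (percentile intervals, split R-hat over chains)."""
    return summarize_draws(np.asarray(draws, float), name)


def schedule_trials(n_trials: int, values: tuple[float, ...], rng: np.random.Generator) -> np.ndarray:
    """Distribute pivot-shift values equiproportionally and randomly across a
    block (counts differ by at most one)."""
    reps = np.array([n_trials // len(values)] * len(values))
    reps[: n_trials - reps.sum()] += 1
    out = np.repeat(values, reps)
    rng.shuffle(out)
    return out


@dataclass
class StudyConfig:
    """Configuration of a synthetic study run."""

    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    motion: MotionParams = field(default_factory=MotionParams)
    population: sp.PopulationSpec = field(default_factory=sp.PopulationSpec)
    n_participants: int = 8
    trials_per_block: int = 42
    stimulus: str = "dart"
    pivot_schedule: tuple[float, ...] = PIVOT_SCHEDULES["dart_full"]
    occupancy_slope: float = -0.093
    seed: int = 0
    # MCMC sizing (reduced defaults suitable for desk-scale runs)
    n_steps: int = 2600
    n_burn: int = 1400

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "geometry" in raw:
            kwargs["geometry"] = DisplayGeometry(**raw.pop("geometry"))
        if "motion" in raw:
            kwargs["motion"] = MotionParams(**raw.pop("motion"))
        if "population" in raw:
            kwargs["population"] = sp.PopulationSpec(**raw.pop("population"))
        if "pivot_schedule" in raw:
            raw["pivot_schedule"] = tuple(raw["pivot_schedule"])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        out = dataclasses.asdict(self)
        out["population"]["alpha_mean"] = list(map(float, out["population"]["alpha_mean"]))
        out["population"]["alpha_sd"] = list(map(float, out["population"]["alpha_sd"]))
        if out["population"]["corr"] is not None:
            out["population"]["corr"] = np.asarray(out["population"]["corr"]).tolist()
        out["pivot_schedule"] = list(out["pivot_schedule"])
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh)


def run_synthetic_study(config: StudyConfig) -> dict:
    """End-to-end synthetic study: simulate, analyze, report recovery.

    Deterministic given the config seed.  Returns a dict with the stage
    outputs and a ``report`` DataFrame comparing recovered population
    parameters to their generating values (with coverage flags).
    """
    rng = np.random.default_rng(config.seed)
    profiles = config.population.draw(config.n_participants, rng)
    pop = config.population

    # --- recall stage (measurement level, directions from display geometry)
    recall_df = sp.make_recall_dataset(
        profiles, config.trials_per_block, seed=int(rng.integers(2**31)),
        geometry=config.geometry,
    )
    recall_fit = recall_model.fit_recall(
        recall_df, n_steps=config.n_steps, n_burn=config.n_burn,
        seed=int(rng.integers(2**31)) % 2**16,
    )

    # --- bisection stage: simulate trials + controller, preprocess, fit
    measures = []
    for i, prof in enumerate(profiles):
        for t in range(6):  # a few controller trials per participant
            trial = kinematics.build_trial(
                "bisection", config.stimulus, d=0.0,
                layout_seed=int(rng.integers(2**31)),
                motion_seed=int(rng.integers(2**31)),
                geometry=config.geometry, motion=config.motion,
            )
            series = sp.simulate_bisection_chasee(trial, prof, seed=int(rng.integers(2**31)))
            measures.append(
                bisection_model.preprocess_bisection(trial, series, participant=i, trial_id=t)
            )
    bis_df = pd.DataFrame(measures)
    bis_fit = bisection_model.fit_bisection(
        bis_df, n_steps=config.n_steps, n_burn=config.n_burn,
        seed=int(rng.integers(2**31)) % 2**16,
    )

    # --- LMA stage (occupancy level with the pivot schedule)
    sched = schedule_trials(config.trials_per_block, config.pivot_schedule, rng)
    occ_df = sp.make_occupancy_dataset(
        profiles, config.trials_per_block, d_schedule=sched,
        slope=config.occupancy_slope, seed=int(rng.integers(2**31)),
    )
    occ_fit = lma_model.fit_occupancy(
        occ_df, with_pivot_regression=True,
        n_sweeps=2 * config.n_steps, n_burn=config.n_steps,
        seed=int(rng.integers(2**31)) % 2**16,
    )

    # --- recovery report
    rows = []

    def add(name, summary, truth):
        rows.append(
            {
                "parameter": name,
                "recovered_mean": summary.mean,
                "pi2.5": summary.pi95[0],
                "pi97.5": summary.pi95[1],
                "generating": truth,
                "covered": summary.pi95[0] <= truth <= summary.pi95[1],
                "rhat": summary.rhat,
            }
        )

    for k, p in enumerate(recall_model.PREDICTOR_NAMES):
        add(f"recall mu_{p}", recall_fit.summaries[f"mu_{p}"], pop.alpha_mean[k])
    add("bisection mu_x", bis_fit.summaries["mu_x"], pop.bis_mu_x_mean)
    add("bisection mu_y", bis_fit.summaries["mu_y"], pop.bis_mu_y_mean)
    add("occupancy intercept", occ_fit.summaries["mu_pop"], pop.lma_mu_mean)
    add("occupancy slope", occ_fit.summaries["slope"], config.occupancy_slope)
    report = pd.DataFrame(rows)

    all_rhat = {**recall_fit.rhat, **bis_fit.rhat, **occ_fit.rhat}
    return {
        "recall": recall_fit,
        "bisection": bis_fit,
        "occupancy": occ_fit,
        "recall_data": recall_df,
        "bisection_data": bis_df,
        "occupancy_data": occ_df,
        "report": report,
        "max_rhat": max(all_rhat.values()),
    }


def report_to_json(result: dict, path) -> None:
    payload = {
        "max_rhat": result["max_rhat"],
        "report": result["report"].to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
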