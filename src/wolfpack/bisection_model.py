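"""Distance-bisection analysis: preprocessing and hierarchical displacement fit.

Preprocessing per trial: discard the first 2 s, express the cursor relative
to the nominal midpoint (midpoint of the two agents' pivot points), rotate —
per frame, since the agents move — so the head-on agent lies on the negative
x axis and the perpendicular agent's nose points along +y, average over the
retained frames and multiply both components by 2.  The doubling undoes the
halving of one agent's displacement by the midpoint, so the measure directly
estimates the per-agent perceived displacement (referenced at the pivot).

The hierarchical model gives each participant a bivariate displacement mean
pooled by normal population priors; the regression variant adds the nominal
pivot shift d as a population-level linear predictor on each axis (slope
near one indicates a percept anchored to the agent's body).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sampling import (
    PosteriorSummary,
    build_hier_data,
    check_convergence,
    hier_conditional_draws,
    hier_loglik,
    run_ensemble,
    summarize_draws,
    uniform_bounds_logprior,
)
from .kinematics import HEAD_ON, TrialRecord, InvalidInputError

logger = logging.getLogger("wolfpack")

TRIM_S = 2.0  # discarded at the start of every trial
COEF_BOUND = 5.0
SD_BOUND = 5.0


def preprocess_bisection(
    trial: TrialRecord,
    chasee_series: np.ndarray,
    participant=0,
    trial_id: int = 0,
) -> dict:
    """Reduce one bisection trial to a doubled, rotated displacement measure.

    Returns {"x", "y", "d", "participant", "trial"} with x positive away
    from the head-on agent and y positive along the perpendicular agent's
    orientation.
    """
    if trial.task != "bisection":
        raise InvalidInputError("preprocess_bisection requires a bisection trial")
    series = np.asarray(chasee_series, float)
    if series.shape[0] != trial.n_frames:
        raise InvalidInputError("chasee series length must equal trial frames")
    fps = trial.geometry.frame_rate
    start = int(round(TRIM_S * fps))
    if start >= trial.n_frames:
        raise InvalidInputError("trial shorter than the trim window")

    i_head = trial.conditions.index(HEAD_ON)
    i_perp = 1 - i_head
    piv = trial.pivot[start:]  # (n, 2, 2)
    h = series[start:]
    midpoint = 0.5 * (piv[:, 0] + piv[:, 1])
    disp = h - midpoint

    # per-frame rotation: head-on agent direction -> -x
    u = piv[:, i_head] - midpoint
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    # rotation R maps u to (-1, 0): rows are (-u) and (-u rotated +90)
    x = -(disp[:, 0] * u[:, 0] + disp[:, 1] * u[:, 1])
    y = -(-disp[:, 0] * u[:, 1] + disp[:, 1] * u[:, 0])

    # fix the y sign so +y lies along the perpendicular agent's orientation
    perp_c = np.array([c for c in trial.conditions])
    from .kinematics import assign_orientation

    ori_p = np.empty_like(u)
    for t in range(len(u)):
        ori_p[t] = assign_orientation(
            piv[t, i_perp], h[t], trial.conditions[i_perp], trial.perp_sides[i_perp]
        )
    ori_y = -(-ori_p[:, 0] * u[:, 1] + ori_p[:, 1] * u[:, 0])
    sign = np.where(ori_y >= 0, 1.0, -1.0)
    y = y * sign

    return {
        "participant": participant,
        "trial": trial_id,
        "d": trial.d,
        "x": 2.0 * float(np.mean(x)),
        "y": 2.0 * float(np.mean(y)),
    }


def _fit_axis(
    df: pd.DataFrame,
    col: str,
    with_pivot_regression: bool,
    n_steps: int,
    n_burn: int,
    seed: int,
):
    pids = df["participant"].to_numpy()
    y = df[col].to_numpy(float)
    d = df["d"].to_numpy(float)
    if with_pivot_regression:
        Z = np.column_stack([np.ones_like(y), d])
        n_fixed = 1
    else:
        Z = np.ones((len(y), 1))
        n_fixed = 0
    data = build_hier_data(pids, Z, y, np.zeros(len(y), int), k_hier=1, n_groups=1)
    if data.n_participants < 2:
        raise InvalidInputError("need at least 2 participants")

    lo = np.concatenate([[-COEF_BOUND, 1e-4], -COEF_BOUND * np.ones(n_fixed), [1e-3]])
    hi = np.concatenate([[COEF_BOUND, SD_BOUND], COEF_BOUND * np.ones(n_fixed), [SD_BOUND]])

    def log_prob(theta):
        lp = uniform_bounds_logprior(theta, lo, hi)
        if not np.isfinite(lp):
            return -np.inf
        mu, sig = theta[0], theta[1]
        beta = theta[2 : 2 + n_fixed]
        s2 = np.array([theta[-1] ** 2])
        return lp + hier_loglik(data, np.array([mu]), np.array([[sig**2]]), beta, s2)

    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    x0 = np.concatenate([[coef[0], 0.2], coef[1:], [max(float(np.std(y - Z @ coef)), 0.05)]])
    scales = np.concatenate([[0.1, 0.05], 0.1 * np.ones(n_fixed), [0.05]])
    chain = run_ensemble(log_prob, x0, scales, n_steps=n_steps, n_burn=n_burn, seed=seed)
    names = [f"mu_{col}", f"sigma_{col}"] + ([f"slope_{col}"] if n_fixed else []) + [f"resid_sd_{col}"]
    draws = {name: chain[:, :, j] for j, name in enumerate(names)}
    return draws, data, chain


@dataclass
class BisectionFit:
    summaries: dict[str, PosteriorSummary]
    draws: dict[str, np.ndarray]
    participant_means: pd.DataFrame
    rhat: dict[str, float]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": s.name,
                    "mean": s.mean,
                    "pi2.5": s.pi95[0],
                    "pi97.5": s.pi95[1],
                    "rhat": s.rhat,
                }
                for s in self.summaries.values()
            ]
        )


def fit_bisection(
    measures: pd.DataFrame,
    with_pivot_regression: bool = False,
    n_steps: int = 2000,
    n_burn: int = 1000,
    seed: int = 0,
    check: bool = True,
) -> BisectionFit:
    """Hierarchical bivariate displacement fit (x and y axes independent).

    ``measures`` columns: participant, trial, d, x, y (degrees, doubled).
    With ``with_pivot_regression`` the population mean of each axis is
    offset + slope * d.
    """
    draws: dict[str, np.ndarray] = {}
    pm = {}
    for i, col in enumerate(("x", "y")):
        dr, data, chain = _fit_axis(
            measures, col, with_pivot_regression, n_steps, n_burn, seed + i
        )
        draws.update(dr)
        rng = np.random.default_rng(seed + 10 + i)
        flat = chain.reshape(-1, chain.shape[-1])
        take = rng.choice(len(flat), size=min(200, len(flat)), replace=False)
        n_fixed = 1 if with_pivot_regression else 0
        acc = np.zeros((data.n_participants, 1))
        for t in flat[take]:
            acc += hier_conditional_draws(
                data,
                np.array([t[0]]),
                np.array([[t[1] ** 2]]),
                t[2 : 2 + n_fixed],
                np.array([t[-1] ** 2]),
                rng,
            )
        pm[col] = acc[:, 0] / len(take)
        pm["participant"] = data.participants
    rhat = check_convergence(draws, raise_on_fail=check)
    summaries = {n_: summarize_draws(a, n_) for n_, a in draws.items()}
    participant_means = pd.DataFrame(
        {"participant": pm["participant"], "mu_x": pm["x"], "mu_y": pm["y"]}
    )
    return BisectionFit(summaries, draws, participant_means, rhat)


def implied_midpoint_shift(slope: float) -> float:
    """Cursor shift per degree of agent displacement: one displaced agent
    moves the true perceived midpoint by half its shift."""
    if not np.isfinite(slope):
        raise InvalidInputError("slope must be finite")
    return slope / 2.0
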