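"""Net-force model of cursor placement in the avoidance task.

Each agent repels the chasee with an inverse-square force

    F_a(h) = (1 / r^2) [cos phi, sin phi]

where phi is the angle of the vector from the agent's force origin g toward
the evaluation point h and r = |h - g|.  The display boundary contributes
c * F_boundary(h) with magnitude (1/r^2 - 1/2) directed from the display
center toward h; the weight c captures how strongly a participant avoids the
boundary.  Cursor placement is modeled as settling at low-|F_net| points.

The displacement analysis detects dwell events in the cursor series (slow,
sustained episodes), evaluates |F_net| at the cursor position during events
against lagged agent positions whose force origins are shifted forward along
each agent's orientation by a candidate displacement d_f, and finds, per
participant, the (c, d_f) grid point minimizing the median |F_net|.  The
per-participant displacement minima are pooled with a location-scale
Student-t model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._sampling import PosteriorSummary, run_ensemble, summarize_draws

logger = logging.getLogger("wolfpack")

SPEED_THRESHOLD = 15.0  # degrees / s
MIN_EVENT_S = 0.3  # dwell events must last at least this long
DEFAULT_D_GRID = np.round(np.arange(-0.2, 0.5001, 0.05), 10)
DEFAULT_C_GRID = np.concatenate([[0.0], np.geomspace(0.05, 10.0, 24)])


class SingularPointError(ValueError):
    pass


def boundary_magnitude(r: np.ndarray) -> np.ndarray:
    """Boundary force magnitude (1/r^2 - 1/2); configurable hook."""
    return 1.0 / r**2 - 0.5


@dataclass
class ForceField:
    """Agent force origins plus boundary weighting."""

    origins: np.ndarray  # (A, 2) force origins (perceived agent centers)
    c: float = 0.0  # boundary weight, >= 0
    boundary_fn: Callable[[np.ndarray], np.ndarray] = boundary_magnitude

    def __post_init__(self):
        self.origins = np.atleast_2d(np.asarray(self.origins, dtype=float))
        if self.c < 0:
            raise ValueError("boundary weight c must be >= 0")


def net_force(h: np.ndarray, field: ForceField) -> np.ndarray:
    """Net force vector at point(s) h; h may be (2,) or (N, 2)."""
    h = np.asarray(h, dtype=float)
    single = h.ndim == 1
    hh = np.atleast_2d(h)
    delta = hh[:, None, :] - field.origins[None, :, :]  # (N, A, 2)
    r = np.linalg.norm(delta, axis=-1)  # (N, A)
    if np.any(r < 1e-9):
        raise SingularPointError("net force evaluated at an agent force origin")
    F = (delta / r[..., None] / (r**2)[..., None]).sum(axis=1)  # (N, 2)
    if field.c > 0:
        rb = np.linalg.norm(hh, axis=-1)
        if np.any(rb < 1e-9):
            raise SingularPointError("boundary force evaluated at display center")
        F = F + field.c * field.boundary_fn(rb)[:, None] * (hh / rb[:, None])
    return F[0] if single else F


def net_force_batch(h: np.ndarray, origins: np.ndarray, c: np.ndarray | float) -> np.ndarray:
    """Vectorized |F_net| for many (h, origins) pairs at once.

    h: (N, 2); origins: (N, A, 2); c scalar or (N,).  Returns forces (N, 2).
    """
    delta = h[:, None, :] - origins  # (N, A, 2)
    r2 = np.einsum("nak,nak->na", delta, delta)
    r2 = np.maximum(r2, 1e-18)
    F = np.einsum("nak,na->nk", delta, r2**-1.5)
    rb = np.linalg.norm(h, axis=-1)
    rb = np.maximum(rb, 1e-9)
    mag = boundary_magnitude(rb)
    F = F + np.asarray(c)[..., None] * mag[:, None] * (h / rb[:, None])
    return F


@dataclass
class DwellEvent:
    """A sustained slow-cursor episode."""

    onset: int  # frame index
    offset: int  # exclusive
    trial: int = 0
    participant: object = None
    is_first: bool = False  # first event of a trial (excluded downstream)

    @property
    def n_frames(self) -> int:
        return self.offset - self.onset


def cursor_speed(chasee_series: np.ndarray, frame_rate: float) -> np.ndarray:
    """Per-frame speed (deg/s), Gaussian-smoothed with sigma = 1 frame.

    The speed series has length n-1; speed[t] is the speed of the step from
    frame t to t+1.
    """
    steps = np.diff(np.asarray(chasee_series, float), axis=0)
    speed = np.linalg.norm(steps, axis=1) * frame_rate
    return gaussian_filter1d(speed, sigma=1.0, truncate=4.0)


def detect_events(
    chasee_series: np.ndarray, frame_rate: float, trial: int = 0, participant=None
) -> list[DwellEvent]:
    """Find dwell events: runs of smoothed speed below 15 deg/s lasting at
    least 300 ms.  The first event of each trial is flagged (it reflects the
    computer-chosen start position and is excluded from analysis)."""
    series = np.asarray(chasee_series, float)
    if len(series) < 2:
        return []
    speed = cursor_speed(series, frame_rate)
    slow = speed < SPEED_THRESHOLD
    min_frames = int(np.ceil(MIN_EVENT_S * frame_rate))
    events: list[DwellEvent] = []
    t = 0
    n = len(slow)
    while t < n:
        if slow[t]:
            start = t
            while t < n and slow[t]:
                t += 1
            if t - start >= min_frames:
                events.append(
                    DwellEvent(
                        onset=start,
                        offset=t,
                        trial=trial,
                        participant=participant,
                        is_first=not events,
                    )
                )
        else:
            t += 1
    return events


def find_equilibrium(
    start: np.ndarray,
    field: ForceField,
    step: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 20000,
    boundary_radius: float = 11.75,
) -> dict:
    """Follow the force field from ``start`` to a zero-net-force point.

    Returns {"point", "force_mag", "converged", "escaped"}.
    """
    h = np.asarray(start, dtype=float).copy()
    for _ in range(max_iter):
        F = net_force(h, field)
        mag = np.linalg.norm(F)
        if mag < tol:
            return {"point": h, "force_mag": mag, "converged": True, "escaped": False}
        h = h + step * F / max(mag, 1.0)  # normalized step for stiff regions
        if np.linalg.norm(h) > boundary_radius:
            return {"point": h, "force_mag": mag, "converged": False, "escaped": True}
    return {"point": h, "force_mag": float(np.linalg.norm(net_force(h, field))), "converged": False, "escaped": False}


def _event_force_table(
    trials: Sequence,
    chasee_series: Sequence[np.ndarray],
    lag_ms: float,
    offset_ms: float,
    d_grid: np.ndarray,
    c_grid: np.ndarray,
) -> np.ndarray | None:
    """Median |F_net| over all events for one participant's trials.

    Returns array (len(c_grid), len(d_grid)) or None if no usable events.
    """
    fps = trials[0].geometry.frame_rate
    off_f = int(round(offset_ms / 1000.0 * fps))
    lag_f = int(round(lag_ms / 1000.0 * fps))

    h_list, ref_list, ori_list = [], [], []
    for trial, series in zip(trials, chasee_series):
        events = detect_events(series, fps)
        for ev in events:
            if ev.is_first:
                continue
            t_h = min(ev.onset + off_f, trial.n_frames - 1)
            t_g = max(t_h - lag_f, 0)  # agents seen one lag earlier
            h_list.append(series[t_h])
            ori = trial.orientations_at(t_g, chasee_pos=series[t_g])
            ref = trial.pivot[t_g] + trial.d * ori
            ref_list.append(ref)
            ori_list.append(ori)
    if not h_list:
        return None
    h = np.array(h_list)  # (E, 2)
    ref = np.array(ref_list)  # (E, A, 2)
    ori = np.array(ori_list)
    E = len(h)
    med = np.empty((len(c_grid), len(d_grid)))
    for j, d_f in enumerate(d_grid):
        origins = ref + d_f * ori
        delta = h[:, None, :] - origins
        r2 = np.maximum(np.einsum("eak,eak->ea", delta, delta), 1e-18)
        F_ag = np.einsum("eak,ea->ek", delta, r2**-1.5)  # (E, 2)
        rb = np.maximum(np.linalg.norm(h, axis=1), 1e-9)
        Fb = boundary_magnitude(rb)[:, None] * (h / rb[:, None])
        for i, c in enumerate(c_grid):
            F = F_ag + c * Fb
            med[i, j] = np.median(np.linalg.norm(F, axis=1))
    return med


def field_grid(
    field: ForceField,
    extent: float = 11.75,
    step: float = 0.5,
) -> pd.DataFrame:
    """Sample the net force on a square grid (for visualization export).

    Returns a DataFrame with columns x, y, fx, fy, magnitude; grid points
    at singularities are dropped.
    """
    xs = np.arange(-extent, extent + step / 2, step)
    rows = []
    for x in xs:
        for y in xs:
            h = np.array([x, y])
            try:
                f = net_force(h, field)
            except SingularPointError:
                continue
            rows.append({"x": x, "y": y, "fx": f[0], "fy": f[1],
                         "magnitude": float(np.linalg.norm(f))})
    return pd.DataFrame(rows)


def fit_student_t(
    values: np.ndarray,
    seed: int = 0,
    n_steps: int = 1500,
    n_burn: int = 700,
) -> dict:
    """Location-scale Student-t fit of per-participant displacement minima.

    Posterior sampled over (location, log scale, log nu) with flat bounded
    priors; returns summaries and draws of the location.
    """
    values = np.asarray(values, float)
    from scipy.stats import t as t_dist

    lo = np.array([-2.0, np.log(1e-3), np.log(1.0)])
    hi = np.array([2.0, np.log(5.0), np.log(100.0)])

    def log_prob(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        loc, log_s, log_nu = theta
        return float(np.sum(t_dist.logpdf(values, np.exp(log_nu), loc=loc, scale=np.exp(log_s))))

    x0 = np.array([np.median(values), np.log(max(values.std(), 0.02)), np.log(5.0)])
    scales = np.array([0.05, 0.3, 0.3])
    chain = run_ensemble(log_prob, x0, scales, n_steps=n_steps, n_burn=n_burn, seed=seed)
    loc_draws = chain[:, :, 0]
    return {
        "summary": summarize_draws(loc_draws, "displacement_mean"),
        "draws": loc_draws,
    }


def estimate_displacement(
    trials_by_participant: dict,
    chasee_by_participant: dict,
    lag_ms: float = 200.0,
    offset_ms: float = 100.0,
    d_grid: np.ndarray = DEFAULT_D_GRID,
    c_grid: np.ndarray = DEFAULT_C_GRID,
    seed: int = 0,
) -> dict:
    """Full displacement analysis over a set of participants.

    For each participant: detect dwell events, evaluate the median |F_net|
    over the (c, d_f) grid at ``offset_ms`` after event onset with agent
    positions ``lag_ms`` earlier, pick c by grid search (minimum median
    magnitude), then the displacement as the argmin over d_f at that c (ties
    resolved toward the smallest d_f).  Participant minima are pooled with a
    Student-t model.

    Returns {"participants": DataFrame, "population": PosteriorSummary,
    "draws": ...}.
    """
    d_grid = np.asarray(d_grid, float)
    c_grid = np.asarray(c_grid, float)
    rows = []
    for pid, trials in trials_by_participant.items():
        med = _event_force_table(
            trials, chasee_by_participant[pid], lag_ms, offset_ms, d_grid, c_grid
        )
        if med is None:
            logger.warning("participant %s has no usable dwell events; dropped", pid)
            continue
        ci = int(np.argmin(med.min(axis=1)))
        di = int(np.argmin(med[ci]))  # np.argmin returns first (smallest d) on ties
        rows.append(
            {
                "participant": pid,
                "c": c_grid[ci],
                "d_min": d_grid[di],
                "median_force": med[ci, di],
            }
        )
    participants = pd.DataFrame(rows)
    if participants.empty:
        raise ValueError("no participants with usable dwell events")
    fit = fit_student_t(participants["d_min"].to_numpy(), seed=seed)
    return {
        "participants": participants,
        "population": fit["summary"],
        "draws": fit["draws"],
    }
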