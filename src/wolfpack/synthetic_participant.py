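"""Synthetic participants: behavioral generators with known ground truth.

Every downstream analysis stage is exercised against data generated here, so
each generator reproduces exactly the statistical structure the corresponding
model assumes:

* the LMA chasee controller descends the net-force field of the perceived
  agent centers (a first-order controller with perception-action lag and
  motor noise);
* the bisection controller tracks the midpoint of the two perceived agent
  centers with a first-order lag;
* recall judgments follow the additive four-factor vector model with
  bivariate Gaussian noise;
* per-trial wolfpack occupancy follows the beta model parameterized by mean
  proportion and concentration (sample size).

A perceived agent center is always a fixed body-frame point: the sprite
reference point shifted forward along the nose/eye axis by the participant's
perceived displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinematics as kin
from .forcefield import ForceField, net_force_batch
from .kinematics import HEAD_ON, PERPENDICULAR, TrialRecord

logger = logging.getLogger("wolfpack")

PREDICTORS = ("gravity", "momentum", "hand_inertia", "orientation")


@dataclass
class ParticipantProfile:
    """Ground-truth parameters of one synthetic participant."""

    # recall: displacement magnitudes (deg) for gravity, momentum,
    # hand inertia and orientation, plus isotropic recall noise
    alpha: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.3, 0.14]))
    noise_sd: float = 1.0
    # bisection: true per-agent displacement along the nose (head-on agent,
    # perpendicular agent) and tracking noise
    bis_mu_x: float = 0.25
    bis_mu_y: float = 0.1
    bis_noise_sd: float = 0.05
    bis_rate: float = 8.0  # first-order tracking rate, 1/s (None = instant)
    # LMA occupancy (beta within-participant model)
    lma_mu: float = 0.5
    lma_kappa: float = 30.0
    # controller
    c_boundary: float = 1.0
    d_perceived: float = 0.0  # forward shift of the perceived center, deg
    motor_noise: float = 0.02  # per-frame positional noise, deg
    mobility: float = 150.0  # cursor speed per unit net force, deg/s
    max_speed: float = 30.0  # cursor speed cap, deg/s
    n_substeps: int = 3  # integration substeps per frame (stability)
    # intermittent relocation bursts (dwell-and-jump movement style)
    burst_rate: float = 0.8  # bursts per second (Poisson)
    burst_duration: float = 0.25  # s
    burst_gain: float = 6.0  # mobility multiplier during a burst

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.noise_sd <= 0 or self.bis_noise_sd <= 0:
            raise ValueError("noise sds must be > 0")
        if not 0 < self.lma_mu < 1:
            raise ValueError("lma_mu must be in (0, 1)")
        if self.lma_kappa <= 0:
            raise ValueError("lma_kappa must be > 0")


def _logit(p):
    return np.log(p / (1 - p))


def _ilogit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PopulationSpec:
    """Population distribution from which participant profiles are drawn.

    ``corr`` couples (orientation alpha, bisection head-on displacement,
    logit LMA occupancy) across participants, as used by the cross-task
    model.
    """

    # recall coefficients: population means and between-participant sds
    # (sds sized so that a ~20-participant mean has the study's precision)
    alpha_mean: np.ndarray = field(default_factory=lambda: np.array([0.01, -0.02, 0.26, 0.14]))
    alpha_sd: np.ndarray = field(default_factory=lambda: np.array([0.49, 0.29, 0.65, 0.32]))
    noise_sd: float = 1.0
    bis_mu_x_mean: float = 0.25
    bis_mu_x_sd: float = 0.3
    bis_mu_y_mean: float = 0.1
    bis_mu_y_sd: float = 0.25
    bis_noise_sd: float = 0.05
    lma_mu_mean: float = 0.5
    lma_mu_sd: float = 0.025  # sd on the logit scale is derived from this
    lma_kappa: float = 30.0
    d_perceived_mean: float = 0.13
    d_perceived_sd: float = 0.05
    c_boundary_range: tuple[float, float] = (0.3, 2.5)  # boundary-avoidance spread
    corr: np.ndarray | None = None  # 3x3 for (alpha_ori, bis_mu_x, logit lma_mu)

    def __post_init__(self):
        self.alpha_mean = np.asarray(self.alpha_mean, float)
        self.alpha_sd = np.asarray(self.alpha_sd, float)
        if self.corr is not None:
            self.corr = np.asarray(self.corr, float)
            if not np.allclose(np.diag(self.corr), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.any(np.linalg.eigvalsh(self.corr) <= 0):
                raise ValueError("correlation matrix must be positive definite")

    def draw(self, n: int, seed: int | np.random.Generator) -> list[ParticipantProfile]:
        """Draw n participant profiles honoring the correlation structure."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # correlated triple: orientation alpha, bisection mu_x, logit occupancy
        g_mean = _logit(self.lma_mu_mean)
        # delta-method sd on the logit scale
        g_sd = self.lma_mu_sd / (self.lma_mu_mean * (1 - self.lma_mu_mean))
        means = np.array([self.alpha_mean[3], self.bis_mu_x_mean, g_mean])
        sds = np.array([self.alpha_sd[3], self.bis_mu_x_sd, g_sd])
        C = self.corr if self.corr is not None else np.eye(3)
        cov = C * np.outer(sds, sds)
        triples = rng.multivariate_normal(means, cov, size=n)
        profiles = []
        for i in range(n):
            alpha = self.alpha_mean + self.alpha_sd * rng.standard_normal(4)
            alpha[3] = triples[i, 0]
            mu = float(np.clip(_ilogit(triples[i, 2]), 1e-3, 1 - 1e-3))
            profiles.append(
                ParticipantProfile(
                    alpha=alpha,
                    noise_sd=self.noise_sd,
                    bis_mu_x=float(triples[i, 1]),
                    bis_mu_y=float(rng.normal(self.bis_mu_y_mean, self.bis_mu_y_sd)),
                    bis_noise_sd=self.bis_noise_sd,
                    lma_mu=mu,
                    lma_kappa=self.lma_kappa,
                    d_perceived=float(rng.normal(self.d_perceived_mean, self.d_perceived_sd)),
                    c_boundary=float(rng.uniform(*self.c_boundary_range)),
                )
            )
        return profiles


# ---------------------------------------------------------------------------
# Controllers
# ---------------------------------------------------------------------------


def simulate_lma_chasee(
    trial: TrialRecord,
    profile: ParticipantProfile,
    lag_ms: float = 200.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Drive the chasee down the net-force field of perceived agent centers.

    Per frame the controller perceives each agent's center at
    ref_pos + d_perceived * orientation (a fixed body-frame point), computes
    the net force from agent positions one perception-action lag earlier, and
    steps along the force with bounded speed plus Gaussian motor noise.  The
    trajectory stays inside the display boundary.
    """
    if trial.task not in ("LMA", "recall_probe"):
        raise ValueError("simulate_lma_chasee requires an LMA trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fps = trial.geometry.frame_rate
    n = trial.n_frames
    lag_f = int(round(lag_ms / 1000.0 * fps))
    dt = 1.0 / fps
    rmax = trial.geometry.boundary_radius

    perp = np.array(trial.perp_sides, dtype=float)
    is_perp = np.array([c == PERPENDICULAR for c in trial.conditions])
    shift = trial.d + profile.d_perceived  # forward shift of origins from pivots

    chasee = np.empty((n, 2))
    chasee[0] = trial.chasee[0]
    noise = profile.motor_noise * rng.standard_normal((n, 2))
    burst_frames = max(int(round(profile.burst_duration * fps)), 1)
    burst_left = 0
    for t in range(1, n):
        tl = max(t - 1 - lag_f, 0)  # clamp lag to the first frame
        piv = trial.pivot[tl]
        delta = chasee[tl] - piv
        norm = np.linalg.norm(delta, axis=1, keepdims=True)
        norm = np.maximum(norm, 1e-9)
        ori = delta / norm
        rot = np.stack([-perp * ori[:, 1], perp * ori[:, 0]], axis=-1)
        ori = np.where(is_perp[:, None], rot, ori)
        origins = piv + shift * ori
        if burst_left > 0:
            burst_left -= 1
        elif rng.random() < profile.burst_rate / fps:
            burst_left = burst_frames  # rapid relocation episode
        h = chasee[t - 1]
        sub_dt = dt / profile.n_substeps
        for _ in range(profile.n_substeps):
            F = net_force_batch(h[None, :], origins[None], profile.c_boundary)[0]
            if burst_left > 0:
                # relocation: move at near-cap speed down the force field
                fmag = max(np.linalg.norm(F), 1e-9)
                v = profile.max_speed * 0.9 * F / fmag
            else:
                v = profile.mobility * F
                speed = np.linalg.norm(v)
                if speed > profile.max_speed:
                    v *= profile.max_speed / speed
            h = h + v * sub_dt
        h = h + noise[t]
        r = np.linalg.norm(h)
        if r > rmax:
            h *= rmax / r
        chasee[t] = h
    return chasee


def simulate_bisection_chasee(
    trial: TrialRecord,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Track the midpoint of the two perceived agent centers.

    The perceived center of the head-on agent is its reference point shifted
    by ``bis_mu_x`` along its nose; the perpendicular agent's by ``bis_mu_y``.
    The chasee relaxes toward the perceived midpoint with a first-order lag
    (rate ``bis_rate`` per second; None = instant) plus Gaussian noise.
    """
    if trial.task != "bisection":
        raise ValueError("simulate_bisection_chasee requires a bisection trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fps = trial.geometry.frame_rate
    n = trial.n_frames
    dt = 1.0 / fps
    shifts = np.array(
        [
            profile.bis_mu_x if c == HEAD_ON else profile.bis_mu_y
            for c in trial.conditions
        ]
    )
    chasee = np.empty((n, 2))
    chasee[0] = trial.chasee[0]
    noise = profile.bis_noise_sd * np.sqrt(dt) * rng.standard_normal((n, 2))
    for t in range(1, n):
        piv = trial.pivot[t]
        ori = np.empty((2, 2))
        for a in range(2):
            ori[a] = kin.assign_orientation(
                piv[a], chasee[t - 1], trial.conditions[a], trial.perp_sides[a]
            )
        perceived = piv + (trial.d + shifts)[:, None] * ori
        target = 0.5 * (perceived[0] + perceived[1])
        if profile.bis_rate is None:
            h = target
        else:
            w = min(profile.bis_rate * dt, 1.0)
            h = chasee[t - 1] + w * (target - chasee[t - 1])
        chasee[t] = h + noise[t]
    return chasee


# ---------------------------------------------------------------------------
# Measurement-level generators
# ---------------------------------------------------------------------------


def simulate_recall_judgment(
    true_ref_pos: np.ndarray,
    predictor_dirs: np.ndarray,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One recall judgment: truth + sum of directional displacements + noise.

    ``predictor_dirs`` is (4, 2) unit directions (gravity, momentum, hand
    inertia, orientation); rows of NaN mark absent predictors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dirs = np.asarray(predictor_dirs, float)
    present = ~np.isnan(dirs[:, 0])
    offset = (profile.alpha[present, None] * dirs[present]).sum(axis=0)
    eps = profile.noise_sd * rng.standard_normal(2)
    return np.asarray(true_ref_pos, float) + offset + eps


def sample_predictor_directions(
    rng: np.random.Generator,
    geometry: kin.DisplayGeometry = kin.DisplayGeometry(),
) -> tuple[np.ndarray, str]:
    """Draw a realistic set of predictor directions for one recall trial.

    Mimics the final-frame geometry of an avoidance trial: the missing agent
    sits in a random quadrant square, the chasee elsewhere in the display;
    gravity points down, momentum is isotropic, hand inertia points from the
    agent to the chasee, orientation is head-on or perpendicular.
    Returns (directions (4, 2), condition).
    """
    q = int(rng.integers(4))
    b = kin.quadrant_bounds(q, geometry)
    agent = np.array([rng.uniform(b[0], b[1]), rng.uniform(b[2], b[3])])
    while True:
        chasee = rng.uniform(-geometry.boundary_radius, geometry.boundary_radius, 2)
        if np.linalg.norm(chasee) <= geometry.boundary_radius and np.linalg.norm(chasee - agent) > 1.0:
            break
    theta = rng.uniform(0, 2 * np.pi)
    condition = HEAD_ON if rng.random() < 0.5 else PERPENDICULAR
    toward = kin._unit(chasee - agent)
    phi4 = toward if condition == HEAD_ON else kin._rot90(toward, int(rng.choice([-1, 1])))
    hand = kin._unit(chasee - agent)
    dirs = np.array([[0.0, -1.0], [np.cos(theta), np.sin(theta)], hand, phi4])
    return dirs, condition


def make_recall_dataset(
    profiles: list[ParticipantProfile],
    n_trials: int,
    seed: int = 0,
    pivot_shifts: np.ndarray | None = None,
    geometry: kin.DisplayGeometry = kin.DisplayGeometry(),
) -> pd.DataFrame:
    """Measurement-level recall dataset (judgments CSV layout).

    Directions are drawn from :func:`sample_predictor_directions`; the h
    vector is judged minus the reference position, so the true reference
    position can be taken as the origin without loss of generality.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, prof in enumerate(profiles):
        for t in range(n_trials):
            d = 0.0 if pivot_shifts is None else float(pivot_shifts[t % len(pivot_shifts)])
            dirs, condition = sample_predictor_directions(rng, geometry)
            judged = simulate_recall_judgment(np.zeros(2), dirs, prof, rng)
            rows.append(
                {
                    "participant": i,
                    "trial": t,
                    "d": d,
                    "condition": condition,
                    "h_x": judged[0],
                    "h_y": judged[1],
                    **{
                        f"phi{k + 1}": np.rad2deg(np.arctan2(dirs[k, 1], dirs[k, 0]))
                        for k in range(4)
                    },
                }
            )
    return pd.DataFrame(rows)


def simulate_recall_trials(
    profiles: list[ParticipantProfile],
    n_trials: int,
    seed: int = 0,
    d: float = 0.0,
    stimulus: str = "bug",
    duration: float = 4.0,
    lag_ms: float = 200.0,
) -> pd.DataFrame:
    """Recall judgments harvested from fully simulated avoidance trials.

    Each trial runs the stimulus simulator and the net-force controller,
    picks the vanished agent (balancing head-on and perpendicular picks),
    derives the predictor directions from the final frame and generates the
    judgment from the additive vector model.  Short trials suffice: the
    final-frame geometry is what the recall stage consumes, and its
    distribution equilibrates within a few seconds of simulated motion.
    """
    from .recall_model import build_predictors, judgments_to_frame

    rng = np.random.default_rng(seed)
    judgments = []
    for i, prof in enumerate(profiles):
        for t in range(n_trials):
            trial = kin.build_trial(
                "recall_probe",
                stimulus,
                d=d,
                layout_seed=int(rng.integers(2**31)),
                motion_seed=int(rng.integers(2**31)),
                duration=duration,
            )
            chasee = simulate_lma_chasee(trial, prof, lag_ms=lag_ms, seed=rng)
            trial.finalize(chasee)
            prefer = HEAD_ON if t % 2 == 0 else PERPENDICULAR
            a = kin.choose_missing_agent(trial, rng, prefer_condition=prefer)
            last = trial.n_frames - 1
            ori = trial.orientation[last, a]
            ref = trial.pivot[last, a] + trial.d * ori
            mdir = trial.motion_dir[last, a]
            hand = kin._unit(chasee[last] - ref)
            dirs = np.array([[0.0, -1.0], mdir, hand, ori])
            judged = simulate_recall_judgment(ref, dirs, prof, rng)
            rj = build_predictors(trial, judged, participant=i)
            if rj is not None:
                judgments.append(rj)
    return judgments_to_frame(judgments)


def simulate_occupancy(
    profile: ParticipantProfile,
    n_trials: int,
    d: np.ndarray | float = 0.0,
    slope: float = 0.0,
    seed: int | np.random.Generator = 0,
    participant: object = 0,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Per-trial wolfpack occupancy proportions from the beta model.

    w_t ~ Beta(mu_t * kappa, (1 - mu_t) * kappa) with
    mu_t = lma_mu + slope * d_t (identity link, clipped to (eps, 1 - eps)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_arr = np.broadcast_to(np.asarray(d, float), (n_trials,)) if np.ndim(d) == 0 else np.asarray(d, float)
    if len(d_arr) != n_trials:
        d_arr = np.resize(d_arr, n_trials)
    mu = profile.lma_mu + slope * d_arr
    if np.any((mu <= 0) | (mu >= 1)):
        logger.warning("occupancy mean outside (0,1) after pivot shift; clipping")
    mu = np.clip(mu, eps, 1 - eps)
    w = rng.beta(mu * profile.lma_kappa, (1 - mu) * profile.lma_kappa)
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n_trials),
            "d": d_arr,
            "w": w,
        }
    )


def make_occupancy_dataset(
    profiles: list[ParticipantProfile],
    n_trials: int,
    d_schedule: np.ndarray | float = 0.0,
    slope: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    frames = []
    for i, prof in enumerate(profiles):
        frames.append(
            simulate_occupancy(prof, n_trials, d_schedule, slope, rng, participant=i)
        )
    return pd.concat(frames, ignore_index=True)


def make_bisection_measures(
    profiles: list[ParticipantProfile],
    n_trials: int,
    d_schedule: np.ndarray | float = 0.0,
    seed: int = 0,
    trial_noise_sd: float = 0.4,
    pivot_slope: float = 1.0,
) -> pd.DataFrame:
    """Measurement-level bisection dataset (already rotated and doubled).

    Per trial the measure is (pivot_slope * d + bis_mu_x, pivot_slope * d +
    bis_mu_y) plus trial-level noise: the doubling in preprocessing exactly
    undoes the halving of one agent's shift by the midpoint, so a controller
    with per-agent body-frame shifts (a, b) yields measures with mean
    (d + a, d + b) — i.e. pivot_slope = 1 is the body-frame-percept case.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, prof in enumerate(profiles):
        sd = trial_noise_sd
        for t in range(n_trials):
            d = (
                float(np.broadcast_to(d_schedule, (1,))[0])
                if np.ndim(d_schedule) == 0
                else float(np.asarray(d_schedule)[t % len(np.asarray(d_schedule))])
            )
            rows.append(
                {
                    "participant": i,
                    "trial": t,
                    "d": d,
                    "x": pivot_slope * d + prof.bis_mu_x + sd * rng.standard_normal(),
                    "y": pivot_slope * d + prof.bis_mu_y + sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
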