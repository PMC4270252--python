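"""Location-recall displacement analysis.

The recall error vector h (judged minus the reference position of the
vanished agent) is modeled as a linearly additive combination of four
directional factors — representational gravity, representational momentum,
hand inertia and orientation displacement:

    h = sum_k alpha_k [cos phi_k, sin phi_k] + eps,   eps ~ N2(0, diag(sx^2, sy^2))

with the per-participant coefficients alpha_{k,i} pooled by a hierarchical
normal prior alpha_{k,i} ~ N(mu_k, sigma_k^2).  Priors on the population
parameters are uniform on bounded ranges (|mu| <= 5 deg, sds <= 5 deg).

With ``pivot_regression`` the orientation displacement is referenced to the
agent's pivot (the rotation center) rather than the sprite reference point
and regressed on the nominal pivot shift d:

    alpha_4 = mu_4 + beta_4 * d.

A percept anchored to the agent's body then yields a slope near one, because
shifting the sprite away from its pivot moves the perceived center with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sampling import (
    ConvergenceError,
    HierGaussianData,
    PosteriorSummary,
    build_hier_data,
    check_convergence,
    hier_conditional_draws,
    hier_loglik,
    run_ensemble,
    summarize_draws,
    uniform_bounds_logprior,
)
from .kinematics import TrialRecord, InvalidInputError

logger = logging.getLogger("wolfpack")

MAX_ERROR_DEG = 4.0  # judgments farther than this from the truth are dropped
PREDICTOR_NAMES = ("gravity", "momentum", "hand_inertia", "orientation")
COEF_BOUND = 5.0  # uniform prior half-width for displacement magnitudes, deg
SD_BOUND = 5.0


@dataclass
class RecallJudgment:
    """One recall trial in analysis form."""

    h: np.ndarray  # 2-vector, judged - true reference position, deg
    phi: np.ndarray  # (4,) predictor angles, radians; NaN = absent
    d: float
    participant: object
    stimulus: str = "bug"


def build_predictors(trial: TrialRecord, judged_pos: np.ndarray, participant=0) -> RecallJudgment | None:
    """Derive the four predictor directions and the error vector for a trial.

    gravity points straight down; momentum along the missing agent's last
    motion direction; hand inertia from the agent toward the final cursor
    position; orientation along the agent's last orientation.  Static trials
    define only the orientation predictor.  Judgments farther than 4 degrees
    from the reference point are excluded (returns None).
    """
    if trial.missing_agent is None:
        raise InvalidInputError("trial has no missing agent")
    if trial.orientation is None:
        raise InvalidInputError("trial not finalized")
    a = trial.missing_agent
    last = trial.n_frames - 1
    ref = trial.pivot[last, a] + trial.d * trial.orientation[last, a]
    h = np.asarray(judged_pos, float) - ref
    if np.linalg.norm(h) > MAX_ERROR_DEG:
        return None
    ori = trial.orientation[last, a]
    phi = np.full(4, np.nan)
    phi[3] = np.arctan2(ori[1], ori[0])
    if trial.task != "static":
        mdir = trial.motion_dir[last, a]
        phi[0] = -np.pi / 2  # gravity: straight down
        phi[1] = np.arctan2(mdir[1], mdir[0])
        hand = trial.chasee[last] - ref
        if np.linalg.norm(hand) < 1e-9:
            logger.warning("chasee coincides with the missing agent; trial dropped")
            return None
        phi[2] = np.arctan2(hand[1], hand[0])
    return RecallJudgment(h=h, phi=phi, d=trial.d, participant=participant, stimulus=trial.stimulus_kind)


def judgments_to_frame(judgments: list[RecallJudgment]) -> pd.DataFrame:
    """Judgments CSV layout (angles in degrees)."""
    return pd.DataFrame(
        {
            "participant": [j.participant for j in judgments],
            "d": [j.d for j in judgments],
            "h_x": [j.h[0] for j in judgments],
            "h_y": [j.h[1] for j in judgments],
            **{
                f"phi{k + 1}": [np.rad2deg(j.phi[k]) for j in judgments]
                for k in range(4)
            },
        }
    )


@dataclass
class RecallFit:
    """Posterior of the hierarchical four-factor regression."""

    summaries: dict[str, PosteriorSummary]
    draws: dict[str, np.ndarray]  # (chains, draws) population draws
    participant_alpha: pd.DataFrame  # posterior means of alpha_{k,i}
    predictors: tuple[str, ...]
    rhat: dict[str, float]

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": s.name,
                "mean": s.mean,
                "pi2.5": s.pi95[0],
                "pi97.5": s.pi95[1],
                "pi25": s.pi50[0],
                "pi75": s.pi50[1],
                "rhat": s.rhat,
            }
            for s in self.summaries.values()
        ]
        return pd.DataFrame(rows)


def _design_from_frame(
    df: pd.DataFrame, predictors: tuple[str, ...], pivot_regression: bool
):
    """Stacked x/y design rows for the marginalized hierarchical fit."""
    idx = [PREDICTOR_NAMES.index(p) for p in predictors]
    phi = np.deg2rad(df[[f"phi{k + 1}" for k in range(4)]].to_numpy(float))[:, idx]
    if np.isnan(phi).any():
        raise InvalidInputError("NaN predictor angle in the requested predictor set")
    h = df[["h_x", "h_y"]].to_numpy(float)
    d = df["d"].to_numpy(float)
    n = len(df)
    K = len(idx)

    u = np.stack([np.cos(phi), np.sin(phi)], axis=-1)  # (n, K, 2)
    if pivot_regression:
        if "orientation" not in predictors:
            raise InvalidInputError("pivot regression needs the orientation predictor")
        k4 = predictors.index("orientation")
        # reference the orientation displacement to the pivot: h + d * u4
        h = h + d[:, None] * u[:, k4, :]
        extra = d[:, None, None] * u[:, k4, :][:, None, :]  # slope column
        u = np.concatenate([u, extra], axis=1)

    # stack x rows then y rows per judgment
    Z = np.concatenate([u[..., 0], u[..., 1]], axis=0)  # (2n, K[+1])
    y = np.concatenate([h[:, 0], h[:, 1]])
    groups = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    pids = np.concatenate([df["participant"].to_numpy()] * 2)
    return Z, y, groups, pids, K


def fit_recall(
    judgments: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTOR_NAMES,
    pivot_regression: bool = False,
    exclude_zero_pivot: bool = False,
    n_steps: int = 2500,
    n_burn: int = 1200,
    seed: int = 0,
    check: bool = True,
) -> RecallFit:
    """Hierarchical fit of the additive displacement model.

    ``judgments`` uses the CSV layout (participant, d, h_x, h_y, phi1..phi4
    in degrees).  ``predictors`` selects the factor set (e.g. drop gravity
    for darts).  With one participant a non-hierarchical flat-prior fit is
    used.  Raises :class:`ConvergenceError` if any R-hat >= 1.05 (unless
    ``check=False``).
    """
    df = judgments.copy()
    err = np.hypot(df["h_x"], df["h_y"])
    n_dropped = int((err > MAX_ERROR_DEG).sum())
    if n_dropped:
        logger.info("dropping %d judgments with |h| > %g deg", n_dropped, MAX_ERROR_DEG)
        df = df[err <= MAX_ERROR_DEG]
    if exclude_zero_pivot and pivot_regression:
        df = df[df["d"] != 0.0]
    Z, y, groups, pids, K = _design_from_frame(df, predictors, pivot_regression)
    n_fixed = Z.shape[1] - K
    data = build_hier_data(pids, Z, y, groups, k_hier=K, n_groups=2)
    P = data.n_participants

    if P == 1:
        return _fit_single(data, predictors, n_fixed, n_steps, n_burn, seed)
    if P < 2:
        raise InvalidInputError("need at least one participant with data")

    # theta = [mu (K), sigma (K), beta (n_fixed), sx, sy]
    ndim = 2 * K + n_fixed + 2
    lo = np.concatenate([-COEF_BOUND * np.ones(K), 1e-4 * np.ones(K), -COEF_BOUND * np.ones(n_fixed), [1e-3, 1e-3]])
    hi = np.concatenate([COEF_BOUND * np.ones(K), SD_BOUND * np.ones(K), COEF_BOUND * np.ones(n_fixed), [SD_BOUND, SD_BOUND]])

    def log_prob(theta):
        lp = uniform_bounds_logprior(theta, lo, hi)
        if not np.isfinite(lp):
            return -np.inf
        mu = theta[:K]
        sig = theta[K : 2 * K]
        beta = theta[2 * K : 2 * K + n_fixed]
        s2 = theta[-2:] ** 2
        return lp + hier_loglik(data, mu, np.diag(sig**2), beta, s2)

    # moment-based start: pooled least squares
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid_sd = max(float(np.std(y - Z @ coef)), 0.05)
    x0 = np.concatenate([np.clip(coef[:K], -3, 3), 0.3 * np.ones(K), coef[K:], [resid_sd, resid_sd]])
    scales = np.concatenate([0.2 * np.ones(K), 0.1 * np.ones(K), 0.2 * np.ones(n_fixed), [0.1, 0.1]])
    chain = run_ensemble(log_prob, x0, scales, n_steps=n_steps, n_burn=n_burn, seed=seed)

    names = (
        [f"mu_{p}" for p in predictors]
        + [f"sigma_{p}" for p in predictors]
        + (["slope_orientation"] if n_fixed else [])
        + ["resid_sd_x", "resid_sd_y"]
    )
    draws = {name: chain[:, :, j] for j, name in enumerate(names)}
    rhat = check_convergence(draws, raise_on_fail=check)
    summaries = {n_: summarize_draws(a, n_) for n_, a in draws.items()}

    # conditional posterior means of participant coefficients
    rng = np.random.default_rng(seed + 1)
    flat = chain.reshape(-1, ndim)
    take = rng.choice(len(flat), size=min(200, len(flat)), replace=False)
    acc = np.zeros((P, K))
    for t in flat[take]:
        acc += hier_conditional_draws(
            data, t[:K], np.diag(t[K : 2 * K] ** 2), t[2 * K : 2 * K + n_fixed], t[-2:] ** 2, rng
        )
    alpha = acc / len(take)
    participant_alpha = pd.DataFrame(alpha, columns=list(predictors))
    participant_alpha.insert(0, "participant", data.participants)
    return RecallFit(summaries, draws, participant_alpha, predictors, rhat)


def _fit_single(data, predictors, n_fixed, n_steps, n_burn, seed) -> RecallFit:
    """Flat-prior, non-hierarchical fit for a single participant.

    The hierarchy degenerates: the participant coefficient is pinned to the
    population mean (between-participant variance -> 0), leaving a plain
    regression with the bounded-uniform prior."""
    K = data.k_hier
    big = np.diag(np.full(K, 1e-8))

    lo = np.concatenate([-COEF_BOUND * np.ones(K + n_fixed), [1e-3, 1e-3]])
    hi = np.concatenate([COEF_BOUND * np.ones(K + n_fixed), [SD_BOUND, SD_BOUND]])

    def log_prob(theta):
        lp = uniform_bounds_logprior(theta, lo, hi)
        if not np.isfinite(lp):
            return -np.inf
        mu = theta[:K]
        beta = theta[K : K + n_fixed]
        s2 = theta[-2:] ** 2
        return lp + hier_loglik(data, mu, big, beta, s2)

    G = data.G.sum(axis=(0, 1))
    v = data.v.sum(axis=(0, 1))
    coef = np.linalg.solve(G + 1e-9 * np.eye(len(G)), v)
    x0 = np.concatenate([coef, [0.5, 0.5]])
    scales = np.concatenate([0.1 * np.ones(K + n_fixed), [0.05, 0.05]])
    chain = run_ensemble(log_prob, x0, scales, n_steps=n_steps, n_burn=n_burn, seed=seed)
    names = [f"mu_{p}" for p in predictors] + (["slope_orientation"] if n_fixed else []) + ["resid_sd_x", "resid_sd_y"]
    draws = {name: chain[:, :, j] for j, name in enumerate(names)}
    rhat = check_convergence(draws, raise_on_fail=False)
    summaries = {n_: summarize_draws(a, n_) for n_, a in draws.items()}
    alpha = pd.DataFrame([dict(zip(predictors, chain[:, :, :K].reshape(-1, K).mean(axis=0)))])
    alpha.insert(0, "participant", data.participants)
    return RecallFit(summaries, draws, alpha, predictors, rhat)


def fit_static_displacement(
    judgments: pd.DataFrame,
    n_steps: int = 2000,
    n_burn: int = 1000,
    seed: int = 0,
    check: bool = True,
) -> PosteriorSummary:
    """Hierarchical mean of the along-axis (nose-ward) displacement of
    static-stimulus judgments.

    ``judgments`` columns: participant, x (judgment rotated into the agent's
    body frame, nose = +x).  With a single participant falls back to a plain
    normal fit with a warning.
    """
    df = judgments
    pids = df["participant"].to_numpy()
    x = df["x"].to_numpy(float)
    Z = np.ones((len(x), 1))
    data = build_hier_data(pids, Z, x, np.zeros(len(x), int), k_hier=1, n_groups=1)
    single = data.n_participants == 1
    if single:
        logger.warning("single participant: non-hierarchical static fit")

    lo = np.array([-COEF_BOUND, 1e-4, 1e-3])
    hi = np.array([COEF_BOUND, SD_BOUND, SD_BOUND])

    def log_prob(theta):
        lp = uniform_bounds_logprior(theta, lo, hi)
        if not np.isfinite(lp):
            return -np.inf
        mu, sig, s = theta
        D = np.array([[1e-8 if single else sig**2]])
        return lp + hier_loglik(data, np.array([mu]), D, np.zeros(0), np.array([s**2]))

    x0 = np.array([float(np.mean(x)), max(float(np.std(x)) / 2, 0.05), max(float(np.std(x)), 0.05)])
    chain = run_ensemble(log_prob, x0, np.array([0.1, 0.05, 0.05]), n_steps=n_steps, n_burn=n_burn, seed=seed)
    draws = {"mu": chain[:, :, 0]}
    check_convergence(draws, raise_on_fail=check and not single)
    return summarize_draws(chain[:, :, 0], "static_displacement")


def rotate_to_body_frame(judged: np.ndarray, ref: np.ndarray, orientation: np.ndarray) -> np.ndarray:
    """Rotate a judgment about the reference point so the nose is +x."""
    delta = np.asarray(judged, float) - np.asarray(ref, float)
    c, s = float(orientation[0]), float(orientation[1])
    return np.array([c * delta[0] + s * delta[1], -s * delta[0] + c * delta[1]])
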