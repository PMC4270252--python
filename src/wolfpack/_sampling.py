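"""Posterior sampling utilities shared by the model-fitting stages.

The hierarchical models in this package are fitted with Markov chain Monte
Carlo.  Linear-Gaussian hierarchies (recall regression, bisection model,
logit-normal occupancy, cross-task joint model) are handled by analytically
integrating out the participant-level coefficients, leaving a low-dimensional
population posterior that is sampled with the affine-invariant ensemble
sampler from :mod:`emcee`.  Participant-level draws are then recovered from
their conjugate conditional distribution.

Conventions: walkers are grouped into four chains for the split-R-hat
convergence diagnostic; posterior summaries report the mean, the 50% and the
95% percentile intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

import emcee

logger = logging.getLogger("wolfpack")

RHAT_LIMIT = 1.05


class ConvergenceError(RuntimeError):
    """Raised when R-hat exceeds the convergence limit for some parameter.

    Carries the offending R-hat table in ``rhat_table``.
    """

    def __init__(self, rhat_table: dict[str, float]):
        self.rhat_table = rhat_table
        worst = max(rhat_table.values())
        super().__init__(
            f"MCMC did not converge: max R-hat = {worst:.3f} "
            f"(limit {RHAT_LIMIT}); table: {rhat_table}"
        )


@dataclass
class PosteriorSummary:
    """Summary of one scalar parameter's posterior distribution."""

    name: str
    mean: float
    pi50: tuple[float, float]
    pi95: tuple[float, float]
    rhat: float | None = None
    ess: float | None = None

    def __str__(self) -> str:  # the paper-style "x, 95% PI [a, b]" format
        return (
            f"{self.name}: {self.mean:.3g}, "
            f"95% PI [{self.pi95[0]:.3g}, {self.pi95[1]:.3g}]"
        )


def summarize_draws(
    draws: np.ndarray, name: str, compute_rhat: bool = True
) -> PosteriorSummary:
    """Summarize posterior draws with shape (chains, draws) or (n,)."""
    draws = np.asarray(draws, dtype=float)
    flat = draws.reshape(-1)
    rhat = ess = None
    if compute_rhat and draws.ndim == 2 and draws.shape[0] >= 2:
        if np.ptp(flat) == 0.0:
            rhat = np.nan  # degenerate (constant) draws: R-hat undefined
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(az.convert_to_dataset(draws))["x"])
                ess = float(az.ess(az.convert_to_dataset(draws))["x"])
    elif draws.ndim == 2 and draws.shape[0] < 2:
        logger.warning("single chain: R-hat omitted for %s", name)
    return PosteriorSummary(
        name=name,
        mean=float(np.mean(flat)),
        pi50=(float(np.percentile(flat, 25)), float(np.percentile(flat, 75))),
        pi95=(float(np.percentile(flat, 2.5)), float(np.percentile(flat, 97.5))),
        rhat=rhat,
        ess=ess,
    )


def check_convergence(
    draws: dict[str, np.ndarray], raise_on_fail: bool = True
) -> dict[str, float]:
    """Split-R-hat for every named (chains, draws[, ...]) array."""
    table: dict[str, float] = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            arr = arr[..., None]
        for j in range(arr.shape[-1]):
            d = arr[..., j]
            if np.ptp(d) == 0.0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table[f"{name}[{j}]" if arr.shape[-1] > 1 else name] = float(
                    az.rhat(az.convert_to_dataset(d))["x"]
                )
    bad = {k: v for k, v in table.items() if not v < RHAT_LIMIT}
    if bad and raise_on_fail:
        raise ConvergenceError(table)
    return table


def run_ensemble(
    log_prob: Callable[[np.ndarray], float],
    x0: np.ndarray,
    scales: np.ndarray,
    n_steps: int = 2000,
    n_burn: int = 1000,
    n_walkers: int | None = None,
    seed: int = 0,
    thin: int = 1,
) -> np.ndarray:
    """Run the ensemble sampler; return draws shaped (4, n_draws, ndim).

    Walkers are initialized in a ball around ``x0`` (re-drawn until the log
    probability is finite) and grouped into 4 chains for diagnostics.
    """
    x0 = np.asarray(x0, dtype=float)
    ndim = x0.size
    if n_walkers is None:
        n_walkers = max(4 * ndim, 16)
    n_walkers += n_walkers % 4  # divisible into 4 chains
    rng = np.random.default_rng(seed)

    p0 = np.empty((n_walkers, ndim))
    for i in range(n_walkers):
        for _ in range(200):
            cand = x0 + scales * rng.standard_normal(ndim) * 0.1
            if np.isfinite(log_prob(cand)):
                p0[i] = cand
                break
        else:
            raise RuntimeError("could not initialize walkers at finite log-prob")

    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler._random = np.random.RandomState(seed)  # reproducible moves
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn, thin=thin)  # (steps, walkers, dim)
    # regroup walkers into 4 chains: (4, steps * walkers/4, dim)
    steps, walkers, _ = chain.shape
    chain = chain.transpose(1, 0, 2).reshape(4, (walkers // 4) * steps, ndim)
    return chain


# ---------------------------------------------------------------------------
# Marginalized hierarchical linear-Gaussian model
#
#   y_i = Xh_i beta_i + Xf_i gamma + eps,   eps_row ~ N(0, s^2_{group(row)})
#   beta_i ~ N(mu, D)          (participant-level coefficients, integrated out)
#   gamma                      (population-level fixed coefficients)
#
# Marginally y_i ~ N(Xh_i mu + Xf_i gamma, Xh_i D Xh_i' + R_i).  The likelihood
# only needs per-participant, per-noise-group Gram statistics, so each
# evaluation costs O(P * K^3) with K small.
# ---------------------------------------------------------------------------


@dataclass
class HierGaussianData:
    """Sufficient statistics for the marginalized hierarchical model."""

    participants: list  # participant labels, order defines index
    G: np.ndarray  # (P, n_groups, K, K) Gram matrices Z' Z per noise group
    v: np.ndarray  # (P, n_groups, K) Z' y
    q: np.ndarray  # (P, n_groups) y' y
    n: np.ndarray  # (P, n_groups) row counts
    k_hier: int  # first k_hier columns of Z are hierarchical, rest fixed

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def k_total(self) -> int:
        return self.G.shape[-1]


def build_hier_data(
    participant_ids: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    k_hier: int,
    n_groups: int | None = None,
) -> HierGaussianData:
    """Assemble per-participant sufficient statistics.

    ``Z`` is the full design (hierarchical columns first), ``y`` the response
    rows, ``groups`` maps each row to a residual-variance group.
    """
    participant_ids = np.asarray(participant_ids)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if n_groups is None:
        n_groups = int(groups.max()) + 1
    labels = list(dict.fromkeys(participant_ids.tolist()))
    P, K = len(labels), Z.shape[1]
    G = np.zeros((P, n_groups, K, K))
    v = np.zeros((P, n_groups, K))
    q = np.zeros((P, n_groups))
    n = np.zeros((P, n_groups))
    index = {lab: i for i, lab in enumerate(labels)}
    for lab, i in index.items():
        rows = participant_ids == lab
        for g in range(n_groups):
            m = rows & (groups == g)
            Zg, yg = Z[m], y[m]
            G[i, g] = Zg.T @ Zg
            v[i, g] = Zg.T @ yg
            q[i, g] = yg @ yg
            n[i, g] = m.sum()
    return HierGaussianData(labels, G, v, q, n, k_hier)


def hier_loglik(
    data: HierGaussianData,
    mu: np.ndarray,
    D: np.ndarray,
    gamma: np.ndarray,
    s2: np.ndarray,
) -> float:
    """Marginal log-likelihood of the population parameters.

    mu: (k_hier,) prior means of the participant coefficients.
    D: (k_hier, k_hier) prior covariance (must be positive definite).
    gamma: (k_total - k_hier,) fixed coefficients.
    s2: (n_groups,) residual variances.
    """
    kh = data.k_hier
    tau = 1.0 / s2  # (n_groups,)
    A = np.einsum("g,pgij->pij", tau, data.G)  # (P, K, K)
    b = np.einsum("g,pgi->pi", tau, data.v)  # (P, K)
    qs = data.q @ tau  # (P,)
    m = np.concatenate([mu, gamma])
    Am = A @ m  # (P, K)
    rRr = qs - 2.0 * (b @ m) + np.einsum("pi,i->p", Am, m)
    c = b[:, :kh] - Am[:, :kh]  # (P, kh)

    try:
        Dinv = np.linalg.inv(D)
        sign, logdetD = np.linalg.slogdet(D)
        if sign <= 0:
            return -np.inf
    except np.linalg.LinAlgError:
        return -np.inf
    M = Dinv[None, :, :] + A[:, :kh, :kh]  # (P, kh, kh)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetM = 2.0 * np.log(np.einsum("pii->pi", L)).sum(axis=1)
    u = np.linalg.solve(L, c[:, :, None])[:, :, 0]
    quad = np.einsum("pi,pi->p", u, u)

    n_rows = data.n.sum(axis=1)
    logdetR = data.n @ np.log(s2)
    ll = -0.5 * np.sum(
        n_rows * np.log(2 * np.pi)
        + logdetR
        + logdetD
        + logdetM
        + rRr
        - quad
    )
    return float(ll)


def hier_conditional_draws(
    data: HierGaussianData,
    mu: np.ndarray,
    D: np.ndarray,
    gamma: np.ndarray,
    s2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of the participant-level coefficients given population params.

    Returns array (P, k_hier).
    """
    kh = data.k_hier
    tau = 1.0 / s2
    A = np.einsum("g,pgij->pij", tau, data.G)
    b = np.einsum("g,pgi->pi", tau, data.v)
    m = np.concatenate([mu, gamma])
    c = b[:, :kh] - (A @ m)[:, :kh]
    Dinv = np.linalg.inv(D)
    M = Dinv[None, :, :] + A[:, :kh, :kh]
    V = np.linalg.inv(M)
    mean = mu[None, :] + np.einsum("pij,pj->pi", V, c)
    Lv = np.linalg.cholesky(V)
    z = rng.standard_normal((data.n_participants, kh))
    return mean + np.einsum("pij,pj->pi", Lv, z)


def uniform_bounds_logprior(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Log-density of independent uniform priors on [lo, hi] (0 or -inf)."""
    if np.all(x >= lo) and np.all(x <= hi):
        return 0.0
    return -np.inf
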