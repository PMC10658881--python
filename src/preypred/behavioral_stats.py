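"""Hierarchical Bayesian regressions and descriptive behavioral metrics.

The regressions model prediction accuracy (Bernoulli, logit link) or
confidence (Beta, logit-mean / concentration parameterization) as a linear
function of an intercept, standardized trial number, and standardized game
number, with non-centered per-subject coefficients

    beta_subject(k) = mu_group(k) + sigma_group(k) * eps_subject(k).

Priors are weakly informative: Normal(0, 1) on group means and subject
offsets, HalfNormal(1) on group SDs.  Posteriors are drawn with an
affine-invariant ensemble sampler (emcee) and summarized with arviz
(mean, 95% HPDI, effective sample size, R-hat).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .hexworld import Environment, HexCell, Trajectory, neighbors

PREDICTORS = ("intercept", "trial", "game")


@dataclass
class HierarchicalRegressionSpec:
    outcome: str = "accuracy"           # "accuracy" (Bernoulli) or "confidence" (Beta)

    def __post_init__(self) -> None:
        if self.outcome not in ("accuracy", "confidence"):
            raise ValueError("outcome must be 'accuracy' or 'confidence'")


@dataclass
class PosteriorSummary:
    table: pd.DataFrame                 # per parameter: mean, hpdi_low, hpdi_high, ess, rhat
    flagged: bool                       # any group-level rhat > 1.05
    idata: object = None

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def fit_hierarchical(data: pd.DataFrame, spec: HierarchicalRegressionSpec,
                     draws: int = 1500, warmup: int = 1500, seed: int = 0,
                     n_walkers: int | None = None,
                     n_steps: int | None = None) -> PosteriorSummary:
    """Fit the hierarchical regression to a long-format data frame.

    ``data`` needs columns ``subject``, ``trial``, ``game`` and the outcome
    column (``correct`` in {0,1} for accuracy; ``confidence`` in [0,1]).
    """
    subjects = np.unique(data["subject"].to_numpy())
    n_sub = len(subjects)
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    sub_idx = pd.Categorical(data["subject"], categories=subjects).codes
    X = np.column_stack([np.ones(len(data)),
                         _zscore(data["trial"].to_numpy(float)),
                         _zscore(data["game"].to_numpy(float))])
    K = X.shape[1]
    if spec.outcome == "accuracy":
        y = data["correct"].to_numpy(float)
        extra = 0
    else:
        n_obs = len(data)
        # squeeze [0,1] ratings into (0,1) for the Beta likelihood
        y = data["confidence"].to_numpy(float) * (n_obs - 1) / n_obs + 0.5 / n_obs
        extra = 1                                  # log concentration

    ndim = 2 * K + n_sub * K + extra
    log_y = np.log(y) if spec.outcome == "confidence" else None
    log_1my = np.log1p(-y) if spec.outcome == "confidence" else None

    def log_prob(theta):
        """Vectorized log posterior for a (B, ndim) batch of walkers."""
        theta = np.atleast_2d(theta)
        B = theta.shape[0]
        mu = theta[:, :K]
        log_sigma = theta[:, K:2 * K]
        eps = theta[:, 2 * K:2 * K + n_sub * K].reshape(B, n_sub, K)
        bad = np.any((log_sigma > 5) | (log_sigma < -12), axis=1)
        sigma = np.exp(np.clip(log_sigma, -12, 5))
        # priors: N(0,1) on mu and eps; HalfNormal(1) on sigma with the
        # log-Jacobian of the log transform
        lp = (-0.5 * np.sum(mu ** 2, axis=1)
              - 0.5 * np.sum(eps ** 2, axis=(1, 2))
              + np.sum(-0.5 * sigma ** 2 + log_sigma, axis=1))
        beta = mu[:, None, :] + sigma[:, None, :] * eps     # (B, S, K)
        eta = np.einsum("nk,bnk->bn", X, beta[:, sub_idx, :])
        if spec.outcome == "accuracy":
            lp += np.sum(y * eta - np.logaddexp(0.0, eta), axis=1)
        else:
            log_kappa = theta[:, -1]
            bad |= (log_kappa <= -3) | (log_kappa >= 8)
            kappa = np.exp(np.clip(log_kappa, -3, 8))[:, None]
            lp += -0.5 * ((log_kappa - 2.0) / 1.5) ** 2
            m = expit(eta)
            a = np.clip(m * kappa, 1e-6, None)
            b = np.clip((1 - m) * kappa, 1e-6, None)
            lp += np.sum(gammaln(a + b) - gammaln(a) - gammaln(b)
                         + (a - 1) * log_y + (b - 1) * log_1my, axis=1)
        lp = np.where(bad | ~np.isfinite(lp), -np.inf, lp)
        return lp

    nw = n_walkers or max(2 * ndim + 2, 64)
    rng = np.random.default_rng(seed)
    p0 = rng.normal(0.0, 0.1, size=(nw, ndim))
    p0[:, K:2 * K] -= 1.0                           # start sigmas small
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob, vectorize=True,
                                    moves=[(emcee.moves.DEMove(), 0.8),
                                           (emcee.moves.DESnookerMove(), 0.2)])
    # pin the proposal RNG (emcee silently ignores anything but a state
    # tuple); the global numpy state must not leak in
    sampler.random_state = np.random.RandomState(seed % (2 ** 31)).get_state()
    # ensemble samplers need long chains in this many dimensions, regardless
    # of walker count; half of each chain is discarded as warmup
    if n_steps is None:
        n_steps = max(2000, 2 * math.ceil((draws + warmup) / nw))
    sampler.run_mcmc(p0, n_steps, progress=False,
                     skip_initial_state_check=True)
    burn = n_steps // 2
    chain = sampler.get_chain(discard=burn)          # (steps, nw, ndim)

    names = []
    cols = []
    for k, p in enumerate(PREDICTORS):
        names.append(f"mu_{p}")
        cols.append(chain[:, :, k])
    for k, p in enumerate(PREDICTORS):
        names.append(f"sigma_{p}")
        cols.append(np.exp(chain[:, :, K + k]))
    if extra:
        names.append("kappa")
        cols.append(np.exp(chain[:, :, -1]))
    idata = az.from_dict({n: c.T for n, c in zip(names, cols)})
    summ = az.summary(idata, hdi_prob=0.95)
    table = pd.DataFrame({
        "mean": summ["mean"],
        "hpdi_low": summ["hdi_2.5%"],
        "hpdi_high": summ["hdi_97.5%"],
        "ess": summ["ess_bulk"],
        "rhat": summ["r_hat"],
    })
    flagged = bool((table["rhat"] > 1.05).any())
    return PosteriorSummary(table=table, flagged=flagged, idata=idata)


# ---------------------------------------------------------------------------
# descriptive metrics
# ---------------------------------------------------------------------------

def _bfs_distance(env: Environment, start: HexCell,
                  targets: frozenset[HexCell]) -> int:
    """Shortest-path move count from ``start`` to any cell in ``targets``."""
    if start in targets:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        cell, d = queue.popleft()
        for _, nxt in neighbors(env, cell):
            if nxt in seen:
                continue
            if nxt in targets:
                return d + 1
            seen.add(nxt)
            queue.append((nxt, d + 1))
    return -1


def max_rich_zone_steps(env: Environment, total_prey_moves: int) -> int:
    """Maximum attainable number of prey steps inside the rich zone, from an
    unconstrained shortest-path search that ignores the predator."""
    if not env.rich_zone:
        raise ValueError("environment has no rich zone")
    d = _bfs_distance(env, env.prey_start, env.rich_zone)
    if d < 0:
        return 0
    return max(0, total_prey_moves - max(d - 1, 0))


def zone_occupancy(traj: Trajectory, env: Environment,
                   total_prey_moves: int | None = None) -> float:
    """Time in the rich zone as a fraction of the maximum attainable time."""
    prey_pos = traj.prey_positions()
    total = total_prey_moves if total_prey_moves is not None else \
        env.moves_per_turn_prey * env.n_turns
    max_steps = max_rich_zone_steps(env, total)
    if max_steps == 0:
        return 0.0
    in_zone = sum(p in env.rich_zone for p in prey_pos)
    return min(1.0, in_zone / max_steps)


def rating_error(ratings, true_weights) -> float:
    """Mean absolute error between ratings and calibrated true weights,
    both on the [-4, 4] scale."""
    r = np.asarray(ratings, float)
    t = np.asarray(true_weights, float)
    if r.shape != t.shape:
        raise ValueError("ratings and truth must align")
    return float(np.mean(np.abs(r - t)))


def rating_error_null(true_weights, n_draws: int = 10000,
                      seed: int = 0) -> np.ndarray:
    """Null distribution of the rating error under uniform-random integer
    ratings on the 9-point scale (-4..4)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(true_weights, float)
    draws = rng.integers(-4, 5, size=(n_draws, len(t))).astype(float)
    return np.mean(np.abs(draws - t), axis=1)
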