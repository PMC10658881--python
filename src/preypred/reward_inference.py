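"""Inverse reinforcement learning: estimating the predator's reward weights.

Five estimators are implemented, in increasing sophistication:

- ``mf_occupancy``  : model-free feature-occupancy counts along the trajectory.
- ``mf_direction``  : model-free counts of features lying along the observed
                      direction of travel (ray to the grid edge / nearest wall).
- ``mf_relative``   : direction counts normalized and differenced against the
                      untaken directions' counts.
- ``maxent_fit``    : infinite-horizon maximum causal entropy IRL -- soft value
                      iteration, expected-visitation propagation, and gradient
                      steps on the feature-expectation mismatch.  Assumes a
                      static feature map (the prey pinned at its position when
                      the trajectory starts), which is exactly why it fails
                      when the predator's goal is the moving prey.
- ``hyptest_fit``   : hypothesis-testing Bayesian IRL -- each candidate weight
                      vector is scored by the likelihood of every observed
                      action under a successor-representation Q function
                      (uniform-policy state-action occupancies, softmax with a
                      sharp temperature of 0.083), with a flat prior on
                      [-1, 1]^3 and an MCMC posterior whose mean is the point
                      estimate.  The reward vector is rebuilt at every step, so
                      a moving prey is handled correctly.

All point estimates are calibrated to the rating scale [-4, 4] by dividing by
the largest absolute entry and multiplying by 4 (zero vectors pass through).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import emcee
import numpy as np

from .hexworld import (DIR_INDEX, DIRECTIONS, N_DIRECTIONS, N_FEATURES,
                       Environment, HexCell, Trajectory, build_mdp,
                       feature_vector, offset_neighbor)

RATING_SCALE = 4.0
HYPTEST_TEMPERATURE = 0.083
SR_DISCOUNT = 0.9


@dataclass
class RewardWeightEstimate:
    point: np.ndarray                     # calibrated to [-4, 4]
    raw: np.ndarray                       # on the estimator's native scale
    model: str
    posterior_samples: np.ndarray | None = None
    converged: bool = True
    iterations: int = 0


def calibrate(weights: np.ndarray, scale: float = RATING_SCALE) -> np.ndarray:
    """Rescale a weight vector so its largest magnitude is ``scale``."""
    w = np.asarray(weights, dtype=float)
    m = np.max(np.abs(w))
    if m == 0:
        return np.zeros_like(w)
    return w / m * scale


# ---------------------------------------------------------------------------
# model-free estimators
# ---------------------------------------------------------------------------

def mf_occupancy(traj: Trajectory, env: Environment) -> RewardWeightEstimate:
    """Sum each feature over the states the predator occupies, with the prey
    feature evaluated against the per-step prey snapshot."""
    steps = traj.predator_steps()
    if not steps:
        raise ValueError("trajectory has no predator steps")
    counts = np.zeros(N_FEATURES)
    for st in steps:
        counts += feature_vector(env, st.next_state, st.prey_at)
    return RewardWeightEstimate(point=calibrate(counts), raw=counts,
                                model="occupancy")


def ray_states(env: Environment, cell: HexCell, direction: str) -> list[HexCell]:
    """Cells traversed by repeating ``direction`` from ``cell`` until the grid
    edge or a wall blocks the line (``cell`` itself excluded)."""
    out = []
    cur = cell
    while True:
        cur = offset_neighbor(cur, direction)
        if not env.is_state(cur):
            break
        out.append(cur)
    return out


def _direction_counts(traj: Trajectory, env: Environment):
    """(observed-ray counts, alternative-ray counts) summed over steps."""
    obs = np.zeros(N_FEATURES)
    alt = np.zeros(N_FEATURES)
    for st in traj.predator_steps():
        for cell in ray_states(env, st.state, st.action):
            obs += feature_vector(env, cell, st.prey_at)
        for d in DIRECTIONS:
            if d == st.action:
                continue
            if not env.is_state(offset_neighbor(st.state, d)):
                continue
            for cell in ray_states(env, st.state, d):
                alt += feature_vector(env, cell, st.prey_at)
    return obs, alt


def _safe_normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else np.zeros_like(v)


def mf_direction(traj: Trajectory, env: Environment,
                 relative: bool = False) -> RewardWeightEstimate:
    """Direction-of-travel feature counts; with ``relative=True`` the counts
    are normalized and differenced against the untaken directions."""
    if not traj.predator_steps():
        raise ValueError("trajectory has no predator steps")
    obs, alt = _direction_counts(traj, env)
    if relative:
        raw = _safe_normalize(obs) - _safe_normalize(alt)
        model = "relative"
    else:
        raw = obs
        model = "direction"
    return RewardWeightEstimate(point=calibrate(raw), raw=raw, model=model)


# ---------------------------------------------------------------------------
# MaxEnt causal entropy IRL
# ---------------------------------------------------------------------------

def softmax_vi(x: np.ndarray) -> float:
    """The soft maximum log Σ exp(x) used by soft value iteration."""
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


@dataclass
class MaxEntWorkspace:
    """Precomputed arrays for MaxEnt on a fixed environment / prey position."""

    features: np.ndarray     # (S, 3) with the prey pinned
    transition: np.ndarray   # (S, 6)
    valid: np.ndarray        # (S, 6)
    discount: float

    @classmethod
    def from_env(cls, env: Environment, prey_at: HexCell,
                 discount: float = SR_DISCOUNT) -> "MaxEntWorkspace":
        mdp = build_mdp(env, np.zeros(N_FEATURES), prey_at, discount)
        return cls(features=mdp.features, transition=mdp.transition,
                   valid=mdp.valid, discount=discount)


def _soft_value_iteration(ws: MaxEntWorkspace, weights: np.ndarray,
                          V0: np.ndarray | None = None, tol: float = 1e-6,
                          max_sweeps: int = 500):
    """Soft value iteration (log-sum-exp backup); returns (V_soft, Q, policy)."""
    S = ws.features.shape[0]
    gamma = ws.discount
    Tc = np.where(ws.valid, ws.transition, 0)
    R = np.zeros((S, N_DIRECTIONS))
    R[ws.valid] = ws.features[ws.transition[ws.valid]] @ weights
    V = np.zeros(S) if V0 is None else V0.copy()
    neg_inf = np.full((S, N_DIRECTIONS), -np.inf)
    for _ in range(max_sweeps):
        Q = np.where(ws.valid, R + gamma * V[Tc], neg_inf)
        m = Q.max(axis=1, initial=-np.inf)
        m = np.where(np.isfinite(m), m, 0.0)
        V_new = m + np.log(np.exp(Q - m[:, None]).sum(axis=1))
        V_new = np.where(ws.valid.any(axis=1), V_new, 0.0)
        if np.max(np.abs(V_new - V)) < tol:
            V = V_new
            break
        V = V_new
    Q = np.where(ws.valid, R + gamma * V[Tc], neg_inf)
    # softmax policy, temperature 1
    m = Q.max(axis=1, initial=-np.inf)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.where(ws.valid, np.exp(Q - m[:, None]), 0.0)
    denom = e.sum(axis=1, keepdims=True)
    policy = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    return V, Q, policy


def _expected_visitation(ws: MaxEntWorkspace, policy: np.ndarray,
                         start: int) -> np.ndarray:
    """Discounted expected state visitation under ``policy`` from ``start``.

    Solves D = d0 + γ Pπᵀ D exactly; ΣD = 1/(1-γ).
    """
    S = policy.shape[0]
    P = np.zeros((S, S))
    for a in range(N_DIRECTIONS):
        va = ws.valid[:, a]
        np.add.at(P, (ws.transition[va, a], np.flatnonzero(va)),
                  policy[va, a])
    d0 = np.zeros(S)
    d0[start] = 1.0
    return np.linalg.solve(np.eye(S) - ws.discount * P, d0)


def maxent_fit(traj: Trajectory, env: Environment, max_iters: int = 1000,
               alpha0: float = 1.0, lam: float = 0.5, tol: float = 1e-4,
               discount: float = SR_DISCOUNT,
               workspace: MaxEntWorkspace | None = None) -> RewardWeightEstimate:
    """Infinite-horizon MaxEnt causal entropy fit of the reward weights.

    The feature map is frozen with the prey at its position at the start of
    the trajectory.  Weights start at zero and follow gradient steps
    ``r += α_k δF`` with α_k = α0 · k^{-λ}, where δF is the difference between
    the mean observed features and the (normalized) expected features of the
    soft-optimal policy.
    """
    steps = traj.predator_steps()
    if not steps:
        raise ValueError("trajectory has no predator steps")
    prey_at = steps[0].prey_at
    ws = workspace or MaxEntWorkspace.from_env(env, prey_at, discount)
    mdp = build_mdp(env, np.zeros(N_FEATURES), prey_at, discount)
    visited = [mdp.index[st.next_state] for st in steps]
    start = mdp.index[steps[0].state]
    F_obs = ws.features[visited].mean(axis=0)
    r = np.zeros(N_FEATURES)
    V = None
    converged = False
    k = 0
    for k in range(1, max_iters + 1):
        # full solve on the first pass; warm-started refinement afterwards
        V, _, policy = _soft_value_iteration(ws, r, V0=V, tol=1e-5,
                                             max_sweeps=300 if k == 1 else 30)
        D = _expected_visitation(ws, policy, start)
        F_hat = (D @ ws.features) / D.sum()
        delta = F_obs - F_hat
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        r = r + alpha0 * k ** (-lam) * delta
        if np.linalg.norm(r) > 50:
            raise RuntimeError("MaxEnt weight estimate diverged")
    return RewardWeightEstimate(point=calibrate(r), raw=r, model="maxent",
                                converged=converged, iterations=k)


# ---------------------------------------------------------------------------
# hypothesis-testing Bayesian IRL
# ---------------------------------------------------------------------------

@dataclass
class SRWorkspace:
    """Successor-representation machinery for one environment.

    ``M`` is the discounted expected state-action occupancy matrix under the
    uniform policy over the objective (deterministic) transitions, from which
    Q(s,a) = M[{s,a}, :] @ R for any reward vector R.  ``static_part`` caches
    M @ Φ for the two static features and ``prey_part[:, p]`` the column for
    the prey feature when the prey sits on state p, so per-step Q values under
    candidate weights are cheap inner products.
    """

    env: Environment
    mdp: object
    sa_state: np.ndarray       # (SA,) state index of each (s, a) pair
    sa_action: np.ndarray      # (SA,) action index
    sa_of: np.ndarray          # (S, 6) -> flat sa index or -1
    static_part: np.ndarray    # (SA, 2)
    prey_part: np.ndarray      # (SA, S)
    discount: float

    @classmethod
    def from_env(cls, env: Environment,
                 discount: float = SR_DISCOUNT) -> "SRWorkspace":
        mdp = build_mdp(env, np.zeros(N_FEATURES), env.prey_start, discount)
        S = mdp.n_states
        pairs = np.argwhere(mdp.valid)
        SA = len(pairs)
        sa_state = pairs[:, 0]
        sa_action = pairs[:, 1]
        sa_of = np.full((S, N_DIRECTIONS), -1, dtype=np.int64)
        sa_of[sa_state, sa_action] = np.arange(SA)
        entered = mdp.transition[sa_state, sa_action]
        # uniform-policy transition over state-action pairs
        n_actions = mdp.valid.sum(axis=1)
        T_sa = np.zeros((SA, SA))
        for i in range(SA):
            s2 = entered[i]
            nxt = sa_of[s2][mdp.valid[s2]]
            T_sa[i, nxt] = 1.0 / n_actions[s2]
        M = np.linalg.inv(np.eye(SA) - discount * T_sa)
        # static features (trees, red ground) of the entered state
        phi_static = mdp.features[entered][:, :2]
        static_part = M @ phi_static
        # column for prey at state p = sum of M columns whose entered state is p
        prey_part = np.zeros((SA, S))
        for i in range(SA):
            prey_part[:, entered[i]] += M[:, i]
        return cls(env=env, mdp=mdp, sa_state=sa_state, sa_action=sa_action,
                   sa_of=sa_of, static_part=static_part, prey_part=prey_part,
                   discount=discount)

    def q_values(self, state_idx: int, prey_idx: int,
                 weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Q over available actions of ``state_idx`` with the prey at
        ``prey_idx``; returns (action indices, Q values)."""
        sa = self.sa_of[state_idx]
        sa = sa[sa >= 0]
        q = (self.static_part[sa] @ weights[:2]
             + self.prey_part[sa, prey_idx] * weights[2])
        return self.sa_action[sa], q


class _HypTestLikelihood:
    """Vectorized per-trajectory action likelihood under the SR Q function.

    Flattens every step's available (s, a) pairs into contiguous arrays so a
    batch of candidate weight vectors is scored with a handful of matrix
    operations (segment log-sum-exp via ``reduceat``).
    """

    def __init__(self, ws: SRWorkspace, step_data, temperature: float):
        self.temperature = temperature
        sa_all, prey_all, starts, chosen = [], [], [], []
        off = 0
        for s_idx, prey_idx, a_idx in step_data:
            sa = ws.sa_of[s_idx]
            sa = sa[sa >= 0]
            n = len(sa)
            sa_all.append(sa)
            prey_all.append(np.full(n, prey_idx))
            starts.append(off)
            pos = int(np.flatnonzero(ws.sa_action[sa] == a_idx)[0])
            chosen.append(off + pos)
            off += n
        sa_all = np.concatenate(sa_all)
        prey_all = np.concatenate(prey_all)
        self.static2 = ws.static_part[sa_all]                 # (n_tot, 2)
        self.preyvec = ws.prey_part[sa_all, prey_all]         # (n_tot,)
        self.starts = np.array(starts)
        self.chosen = np.array(chosen)

    def __call__(self, W: np.ndarray) -> np.ndarray:
        """Log likelihood for a batch of weight vectors ``W`` of shape (b, 3)."""
        W = np.atleast_2d(W)
        q = self.static2 @ W[:, :2].T + self.preyvec[:, None] * W[:, 2]
        z = q / self.temperature
        zmax = np.maximum.reduceat(z, self.starts, axis=0)
        z = z - np.repeat(zmax, np.diff(np.append(self.starts, len(z))), axis=0)
        sums = np.add.reduceat(np.exp(z), self.starts, axis=0)
        return z[self.chosen].sum(axis=0) - np.log(sums).sum(axis=0)


def hyptest_fit(traj: Trajectory, env: Environment, seed: int = 0,
                n_samples: int = 2000, n_warmup: int = 500,
                n_walkers: int = 12, temperature: float = HYPTEST_TEMPERATURE,
                workspace: SRWorkspace | None = None) -> RewardWeightEstimate:
    """Posterior over reward weights by MCMC under the SR action likelihood.

    Flat prior on [-1, 1] per feature; the point estimate is the posterior
    mean, calibrated to [-4, 4].  With no observed actions the posterior
    equals the prior and the point estimate is ~0.
    """
    ws = workspace or SRWorkspace.from_env(env)
    index = ws.mdp.index
    step_data = [(index[st.state], index[st.prey_at], DIR_INDEX[st.action])
                 for st in traj.predator_steps()]
    lik = _HypTestLikelihood(ws, step_data, temperature) if step_data else None

    def log_prob(W):
        W = np.atleast_2d(W)
        out = np.where(np.any(np.abs(W) > 1.0, axis=1), -np.inf, 0.0)
        ok = np.isfinite(out)
        if lik is not None and ok.any():
            out[ok] += lik(W[ok])
        return out

    rng = np.random.default_rng(seed)
    p0 = rng.uniform(-0.5, 0.5, size=(n_walkers, N_FEATURES))
    sampler = emcee.EnsembleSampler(n_walkers, N_FEATURES, log_prob,
                                    vectorize=True)
    # pin the proposal RNG (emcee silently ignores anything but a state
    # tuple); the global numpy state must not leak in
    sampler.random_state = np.random.RandomState(seed % (2 ** 31)).get_state()
    steps_per_walker = max(1, math.ceil((n_warmup + n_samples) / n_walkers))
    burn = max(1, math.ceil(n_warmup / n_walkers))
    sampler.run_mcmc(p0, steps_per_walker + burn, progress=False,
                     skip_initial_state_check=True)
    chain = sampler.get_chain(discard=burn, flat=True)
    post = chain[-n_samples:] if len(chain) > n_samples else chain
    mean = post.mean(axis=0)
    return RewardWeightEstimate(point=calibrate(mean), raw=mean,
                                model="hyptest", posterior_samples=post)


# ---------------------------------------------------------------------------
# rating-fit statistics
# ---------------------------------------------------------------------------

def score_irl(predicted: np.ndarray, ratings: np.ndarray,
              n_params: int) -> tuple[float, float]:
    """(adjusted R², BIC) of pooled model predictions against ratings.

    R² is the squared Pearson correlation; the adjustment is
    1 - (1 - R²)(n - 1)/(n - p - 1).  BIC uses a Gaussian residual model:
    n ln(RSS/n) + p ln n.
    """
    x = np.asarray(predicted, float).ravel()
    y = np.asarray(ratings, float).ravel()
    if x.shape != y.shape:
        raise ValueError("predictions and ratings must align")
    n = len(x)
    if n <= n_params + 1:
        raise ValueError("need n > p + 1 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    rss = float(np.sum((y - x) ** 2))
    bic = n * math.log(max(rss, 1e-300) / n) + n_params * math.log(n)
    return adj, bic
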