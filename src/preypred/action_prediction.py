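"""Observer models of predator-action prediction and their maximum-likelihood fits.

Seven model variants are compared:

- ``repeat``        : expect the predator to repeat its last action.
- ``policy``        : delta-rule learning of per-direction action frequencies,
                      learning rate decaying as α_t = α · n^{-λ}.
- ``policy_gen``    : the same, with the observed one-hot action smoothed by a
                      squared-exponential kernel over the action ring so that
                      adjacent directions share credit.
- ``goal``          : goal inference -- value iteration under the predator's
                      reward weights, Q values passed through softmax (τ=1).
- ``combined``/``combined_gen``/``combined_repeat``:
                      a W-weighted mixture of the goal-inference values and one
                      of the policy learners.

All models map their values to choice probabilities the same way: each
component is min-max rescaled to [0, 1] over the available actions, combined
with weight W, renormalized to a categorical distribution, and mixed with a
small uniform floor (so the one-hot repeat model keeps finite likelihood on
non-repeat choices).  Likelihood is categorical over the participant's
predicted action; learning updates use the predator's actually observed
action and persist across games.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import differential_evolution

from .hexworld import (DIR_INDEX, DIRECTIONS, N_DIRECTIONS, Environment,
                       HexCell, Trajectory, build_mdp)
from .predator_agent import ActionRule, action_probabilities, value_iteration

MODELS = ("repeat", "policy", "policy_gen", "goal",
          "combined", "combined_gen", "combined_repeat")

#: parameter names that are free for each model, in fit order
FREE_PARAMS = {
    "repeat": (),
    "policy": ("alpha", "lam"),
    "policy_gen": ("alpha", "lam"),
    "goal": (),
    "combined": ("W", "alpha", "lam"),
    "combined_gen": ("W", "alpha", "lam"),
    "combined_repeat": ("W",),
}

PARAM_BOUNDS = {"alpha": (1e-3, 1.0), "lam": (0.0, 3.0), "W": (0.0, 1.0)}

DEFAULT_LENGTH_SCALE = 0.02


@dataclass
class LearnerParams:
    alpha: float = 0.5
    lam: float = 0.0
    length_scale: float = DEFAULT_LENGTH_SCALE
    W: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.length_scale <= 0:
            raise ValueError("length scale must be positive")
        if not 0 <= self.W <= 1:
            raise ValueError("W must lie in [0, 1]")


@dataclass
class PolicyEstimate:
    """Running per-direction action-frequency estimate; persists across games."""

    pi: np.ndarray = field(default_factory=lambda: np.zeros(N_DIRECTIONS))
    n: int = 0


def action_kernel(length_scale: float) -> np.ndarray:
    """6x6 smoothing matrix over the action ring.

    Directions sit at angles 0°, 60°, ..., 300°; positions are the angles
    normalized to [0, 1) and distance is the minimal circular difference.
    Rows are normalized to sum to 1 so smoothing conserves the observed
    action's unit mass.
    """
    x = np.arange(N_DIRECTIONS) / N_DIRECTIONS
    d = np.abs(x[:, None] - x[None, :])
    d = np.minimum(d, 1.0 - d)
    k = np.exp(-(d ** 2) / (2.0 * length_scale ** 2))
    return k / k.sum(axis=1, keepdims=True)


def update_policy(est: PolicyEstimate, observed: str, params: LearnerParams,
                  generalize: bool = False) -> PolicyEstimate:
    """Delta-rule update of the action-frequency estimate after one observation."""
    if observed not in DIR_INDEX:
        raise ValueError(f"unknown direction {observed!r}")
    n = est.n + 1
    alpha_t = params.alpha * n ** (-params.lam)
    target = np.zeros(N_DIRECTIONS)
    target[DIR_INDEX[observed]] = 1.0
    if generalize:
        target = action_kernel(params.length_scale)[DIR_INDEX[observed]]
    pi = est.pi + alpha_t * (target - est.pi)
    return PolicyEstimate(pi=pi, n=n)


def predict_goal_inference(env: Environment, weights, state: HexCell,
                           prey_at: HexCell, discount: float = 0.9) -> np.ndarray:
    """Goal-inference prediction: softmax(τ=1) over value-iteration Q values.

    Returns a length-6 probability vector with zeros on unavailable actions.
    """
    mdp = build_mdp(env, weights, prey_at, discount)
    values = value_iteration(mdp)
    dirs, probs = action_probabilities(values, state, ActionRule("softmax", 1.0))
    out = np.zeros(N_DIRECTIONS)
    for d, p in zip(dirs, probs):
        out[DIR_INDEX[d]] = p
    return out


def _rescale(v: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to zeros."""
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


#: uniform floor mixed into every model's choice probabilities
PROB_FLOOR = 1e-2


def combine_predictions(goal: np.ndarray, policy: np.ndarray, W: float,
                        avail: np.ndarray | None = None,
                        floor: float = PROB_FLOOR) -> np.ndarray:
    """Combine goal-inference and policy-learning values into choice probabilities.

    Both components are min-max rescaled over the available actions, mixed as
    ``W * goal + (1 - W) * policy``, renormalized to sum to 1, and mixed with
    a uniform floor.  Returns a length-6 vector with zeros on unavailable
    actions.  A constant (or all-zero) combined vector falls back to uniform.
    """
    if not 0 <= W <= 1:
        raise ValueError("W must lie in [0, 1]")
    if avail is None:
        avail = np.ones(N_DIRECTIONS, dtype=bool)
    g = _rescale(np.asarray(goal, float)[avail])
    p = _rescale(np.asarray(policy, float)[avail])
    v = W * g + (1.0 - W) * p
    n = v.shape[0]
    s = v.sum()
    probs = v / s if s > 0 else np.full(n, 1.0 / n)
    probs = (1.0 - floor) * probs + floor / n
    out = np.zeros(N_DIRECTIONS)
    out[avail] = probs
    return out


@dataclass
class PredictionDataset:
    """Per-trial arrays for one subject's prediction data.

    ``goal_probs`` holds the goal-inference probability vector for the trial's
    state (so fitting never re-solves the MDP); ``observed`` is the predator's
    action, ``predicted`` the participant's prediction, both as direction
    indices.
    """

    avail: np.ndarray          # (T, 6) bool
    goal_probs: np.ndarray     # (T, 6)
    observed: np.ndarray       # (T,) int
    predicted: np.ndarray      # (T,) int
    confidence: np.ndarray | None = None   # (T,) in [0, 1]
    game: np.ndarray | None = None
    trial: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.observed)


@dataclass
class FitResult:
    model: str
    params: dict
    neg_loglik: float
    bic: float
    accuracy: float
    converged: bool = True


def _model_config(model: str) -> tuple[bool, bool, bool]:
    """(uses_goal, generalize, repeat_learner) flags for a model name."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    uses_goal = model in ("goal", "combined", "combined_gen", "combined_repeat")
    generalize = model in ("policy_gen", "combined_gen")
    repeat = model in ("repeat", "combined_repeat")
    return uses_goal, generalize, repeat


@njit(cache=False)
def _nll_core(avail, goal_probs, observed, predicted, W_eff, alpha, lam,
              kernel):
    """Sequential categorical likelihood loop (JIT-compiled).

    The learning update (row of ``kernel`` as the smoothed one-hot target)
    happens *after* the trial's prediction is scored.  Returns (nll, hits).
    """
    T = observed.shape[0]
    pi = np.zeros(N_DIRECTIONS)
    nll = 0.0
    hits = 0
    v = np.empty(N_DIRECTIONS)
    for t in range(T):
        gmin = 1e30
        gmax = -1e30
        pmin = 1e30
        pmax = -1e30
        for a in range(N_DIRECTIONS):
            if avail[t, a]:
                if goal_probs[t, a] < gmin:
                    gmin = goal_probs[t, a]
                if goal_probs[t, a] > gmax:
                    gmax = goal_probs[t, a]
                if pi[a] < pmin:
                    pmin = pi[a]
                if pi[a] > pmax:
                    pmax = pi[a]
        grange = gmax - gmin
        prange = pmax - pmin
        n_av = 0
        vsum = 0.0
        best_a = -1
        best_v = -1e30
        for a in range(N_DIRECTIONS):
            if avail[t, a]:
                g = (goal_probs[t, a] - gmin) / grange if grange > 0 else 0.0
                p = (pi[a] - pmin) / prange if prange > 0 else 0.0
                v[a] = W_eff * g + (1.0 - W_eff) * p
                vsum += v[a]
                n_av += 1
                if v[a] > best_v:
                    best_v = v[a]
                    best_a = a
        pr = predicted[t]
        base = v[pr] / vsum if vsum > 0 else 1.0 / n_av
        nll -= math.log((1.0 - PROB_FLOOR) * base + PROB_FLOOR / n_av)
        if best_a == pr:
            hits += 1
        # learning update from the observed predator action
        a_t = alpha * (t + 1.0) ** (-lam)
        obs = observed[t]
        for a in range(N_DIRECTIONS):
            pi[a] += a_t * (kernel[obs, a] - pi[a])
    return nll, hits


def model_negloglik(data: PredictionDataset, model: str, alpha: float = 0.5,
                    lam: float = 0.0, W: float = 0.5,
                    length_scale: float = DEFAULT_LENGTH_SCALE,
                    return_accuracy: bool = False):
    """Categorical negative log likelihood of a model on one dataset.

    Sequential over trials: the policy estimate is updated from the observed
    predator action *after* the trial's prediction is scored.
    """
    uses_goal, generalize, repeat = _model_config(model)
    if model == "goal":
        W_eff = 1.0
    elif model in ("repeat", "policy", "policy_gen"):
        W_eff = 0.0
    else:
        W_eff = W
    if repeat:
        alpha, lam = 1.0, 0.0
    kernel = (action_kernel(length_scale) if generalize
              else np.eye(N_DIRECTIONS))
    nll, hits = _nll_core(data.avail, data.goal_probs,
                          data.observed.astype(np.int64),
                          data.predicted.astype(np.int64),
                          float(W_eff), float(alpha), float(lam), kernel)
    if return_accuracy:
        return nll, hits / max(len(data), 1)
    return nll


def fit_prediction_model(data: PredictionDataset, model: str, seed: int = 0,
                         length_scale: float = DEFAULT_LENGTH_SCALE,
                         de_maxiter: int = 25, de_popsize: int = 7) -> FitResult:
    """Fit a model's free parameters by differential evolution; returns the
    best parameters, -log L, BIC = k ln N + 2(-L), and categorical accuracy."""
    free = FREE_PARAMS[model]
    N = len(data)
    if N < 1:
        raise ValueError("dataset must contain at least one trial")

    def nll_of(theta) -> float:
        kw = dict(zip(free, theta))
        return model_negloglik(data, model, length_scale=length_scale, **kw)

    converged = True
    if free:
        bounds = [PARAM_BOUNDS[p] for p in free]
        res = differential_evolution(nll_of, bounds, seed=seed, tol=0.01,
                                     maxiter=de_maxiter, popsize=de_popsize,
                                     polish=True, init="sobol")
        theta = res.x
        converged = bool(res.success) or res.nit >= 1
        params = dict(zip(free, theta))
    else:
        params = {}
    nll, acc = model_negloglik(data, model, length_scale=length_scale,
                               return_accuracy=True, **params)
    k = len(free)
    bic = k * math.log(N) + 2.0 * nll
    return FitResult(model=model, params=params, neg_loglik=float(nll),
                     bic=float(bic), accuracy=float(acc), converged=converged)


def fit_all_models(data: PredictionDataset, models=MODELS, seed: int = 0,
                   **kw) -> list[FitResult]:
    return [fit_prediction_model(data, m, seed=seed, **kw) for m in models]


def build_prediction_dataset(env: Environment, traj: Trajectory, weights,
                             predictions: list[str],
                             confidence=None, discount: float = 0.9,
                             goal_cache: dict | None = None) -> PredictionDataset:
    """Assemble a :class:`PredictionDataset` from a predator trajectory and a
    participant's per-move predicted directions.

    ``goal_cache`` (keyed by prey position) avoids re-solving the MDP when the
    predator's reward weights ignore the prey.
    """
    pred_steps = traj.predator_steps()
    if len(pred_steps) != len(predictions):
        raise ValueError("one prediction required per predator move")
    T = len(pred_steps)
    avail = np.zeros((T, N_DIRECTIONS), dtype=bool)
    goal_probs = np.zeros((T, N_DIRECTIONS))
    observed = np.zeros(T, dtype=int)
    predicted = np.zeros(T, dtype=int)
    cache = goal_cache if goal_cache is not None else {}
    weights = np.asarray(weights, dtype=float)
    prey_blind = weights[2] == 0            # prey position cannot change Q
    for t, st in enumerate(pred_steps):
        key = (id(env), None if prey_blind else st.prey_at)
        if key not in cache:
            mdp = build_mdp(env, weights, st.prey_at, discount)
            cache[key] = (mdp, value_iteration(mdp))
        mdp, values = cache[key]
        s = mdp.index[st.state]
        avail[t] = mdp.valid[s]
        dirs, probs = action_probabilities(values, st.state,
                                           ActionRule("softmax", 1.0))
        for d, p in zip(dirs, probs):
            goal_probs[t, DIR_INDEX[d]] = p
        observed[t] = DIR_INDEX[st.action]
        predicted[t] = DIR_INDEX[predictions[t]]
    conf = np.asarray(confidence, float) if confidence is not None else None
    return PredictionDataset(avail=avail, goal_probs=goal_probs,
                             observed=observed, predicted=predicted,
                             confidence=conf)
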