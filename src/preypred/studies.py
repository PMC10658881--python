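"""Desk-scale study drivers reproducing the pipeline's headline patterns.

Each function runs one self-contained computational study on synthetic data
-- IRL estimator validity across preference conditions, observer-weight
recovery, approach/avoid planning patterns, IBS calibration, and
threat-sensitivity dose-response -- and returns plain dictionaries of summary
numbers.  They are used both by the test suite and by the reproduction
script; problem sizes are arguments so callers choose their scale.
"""

from __future__ import annotations

import math
import random
from typing import Sequence

import numpy as np

from .action_prediction import fit_prediction_model
from .hexworld import Environment, HexCell, build_mdp
from .interactive_planning import (PlannerParams, PlanningProblem,
                                   ibs_loglik, planner_ibs_loglik,
                                   simulate_planner_game)
from .predator_agent import ActionRule, value_iteration
from .recovery_harness import (_prediction_base_datasets,
                               _simulate_prediction_dataset)
from .reward_inference import (MaxEntWorkspace, SRWorkspace, hyptest_fit,
                               maxent_fit)
from .synthetic_data import (EnvironmentSpec, exp3_env_spec,
                             generate_environment, simulate_chase)

CONDITION_ORDER = ("trees", "red", "prey")
CONDITION_VECTORS = {"trees": (1.0, 0.0, 0.0), "red": (0.0, 1.0, 0.0),
                     "prey": (0.0, 0.0, 1.0)}

#: opponent softmax temperature assumed by planners in the threat-sensitivity
#: study; matches the decision-noise level typical of fitted human planners
#: in this paradigm
THREAT_STUDY_TAU_OPP = 2.7


# ---------------------------------------------------------------------------
# value iteration against a brute-force oracle
# ---------------------------------------------------------------------------

def finite_horizon_values(mdp, horizon: int) -> np.ndarray:
    """Brute-force finite-horizon dynamic programming oracle for V*.

    Backward induction over ``horizon`` steps; independent of the
    value-iteration implementation it is used to check.
    """
    S = mdp.n_states
    V = np.zeros(S)
    for _ in range(horizon):
        V_next = np.zeros(S)
        for s in range(S):
            best = None
            for a in range(6):
                if mdp.valid[s, a]:
                    q = mdp.reward[s, a] + mdp.discount * V[mdp.transition[s, a]]
                    if best is None or q > best:
                        best = q
            V_next[s] = 0.0 if best is None else best
        V = V_next
    return V


def random_toy_mdp(seed: int, width: int = 5, height: int = 5,
                   discount: float = 0.9):
    """A small random environment + random weights, as a toy MDP."""
    rng = random.Random(seed)
    cells = [HexCell(c, r) for c in range(width) for r in range(height)]
    walls = frozenset(rng.sample(cells, rng.randint(0, 4)))
    free = [c for c in cells if c not in walls]
    pred, prey = rng.sample(free, 2)
    trees = frozenset(rng.sample(free, rng.randint(1, 4)))
    red = frozenset(rng.sample(free, rng.randint(1, 4)))
    env = Environment(width=width, height=height, walls=walls, trees=trees,
                      red_ground=red, predator_start=pred, prey_start=prey)
    weights = [rng.uniform(-1, 1) for _ in range(3)]
    return build_mdp(env, weights, prey, discount)


def value_iteration_oracle_study(n_toys: int = 20, horizon: int = 200,
                                 seed: int = 0) -> dict:
    """Max |V_vi - V_dp| over random toy MDPs, plus the two-cell closed form."""
    max_err = 0.0
    for k in range(n_toys):
        mdp = random_toy_mdp(seed + k)
        vt = value_iteration(mdp, max_iters=500, tol=1e-12)
        oracle = finite_horizon_values(mdp, horizon)
        max_err = max(max_err, float(np.max(np.abs(vt.V - oracle))))
    two = Environment(width=2, height=1,
                      trees=frozenset({HexCell(0, 0), HexCell(1, 0)}),
                      predator_start=HexCell(0, 0), prey_start=HexCell(1, 0))
    mdp2 = build_mdp(two, (1.0, 0.0, 0.0), HexCell(1, 0), 0.9)
    v2 = value_iteration(mdp2, max_iters=500, tol=1e-12).V
    return {"max_abs_error": max_err, "two_cell_value": float(v2[0]),
            "n_toys": n_toys}


# ---------------------------------------------------------------------------
# IRL validity: HypTest succeeds everywhere, MaxEnt fails on the prey
# ---------------------------------------------------------------------------

def _identifies(raw: np.ndarray, true_idx: int) -> bool:
    """An estimate identifies the preferred feature if that feature has the
    largest weight and the weight is positive -- a degenerate near-zero or
    negative vector identifies nothing."""
    return int(np.argmax(raw)) == true_idx and raw[true_idx] > 0


def irl_validity_study(n_seeds: int = 50, n_turns: int = 10,
                       maxent_max_iters: int = 150, seed: int = 0) -> dict:
    """Per-condition success rates of HypTest and MaxEnt at identifying the
    predator's preferred feature from ``2 * n_turns`` observed moves."""
    hyp = {c: 0 for c in CONDITION_ORDER}
    mxe = {c: 0 for c in CONDITION_ORDER}
    for s in range(n_seeds):
        env = generate_environment(EnvironmentSpec(archetype="random",
                                                   seed=seed * 1009 + s))
        srw = SRWorkspace.from_env(env)
        mew = MaxEntWorkspace.from_env(env, env.prey_start)
        for ci, cond in enumerate(CONDITION_ORDER):
            w = CONDITION_VECTORS[cond]
            traj, _ = simulate_chase(env, w, n_turns, ActionRule("max"),
                                     seed=seed * 7919 + 3 * s + ci)
            h = hyptest_fit(traj, env, seed=seed + 31 * s + ci, workspace=srw)
            hyp[cond] += _identifies(h.raw, ci)
            try:
                m = maxent_fit(traj, env, max_iters=maxent_max_iters,
                               workspace=mew)
                mxe[cond] += _identifies(m.raw, ci)
            except RuntimeError:
                pass
    return {"n_seeds": n_seeds,
            "hyptest": {c: hyp[c] / n_seeds for c in CONDITION_ORDER},
            "maxent": {c: mxe[c] / n_seeds for c in CONDITION_ORDER}}


# ---------------------------------------------------------------------------
# observer mixture-weight recovery
# ---------------------------------------------------------------------------

def w_recovery_study(levels: Sequence[float] = (0.1, 0.5, 0.9),
                     n_per_level: int = 5, n_games: int = 25,
                     length_scale: float = 0.15, seed: int = 0) -> dict:
    """Recover the goal-inference weight W of combined-model observers from
    ~``20 * n_games`` trials, plus fitted W on pure goal-inference data."""
    bases = _prediction_base_datasets(n_per_level, seed, n_games, n_turns=10)
    errors = []
    by_level = {}
    for W in levels:
        errs = []
        for j in range(n_per_level):
            data = _simulate_prediction_dataset(
                bases[j], "combined", {"W": W, "alpha": 0.5, "lam": 0.3},
                seed=seed + 997 * j + int(W * 100), length_scale=length_scale)
            fit = fit_prediction_model(data, "combined", seed=seed + j,
                                       length_scale=length_scale)
            errs.append(abs(fit.params["W"] - W))
        by_level[W] = float(np.mean(errs))
        errors.extend(errs)
    goal_ws = []
    for j in range(n_per_level):
        data = _simulate_prediction_dataset(bases[j], "goal", {},
                                            seed=seed + 13 * j,
                                            length_scale=length_scale)
        fit = fit_prediction_model(data, "combined", seed=seed + j,
                                   length_scale=length_scale)
        goal_ws.append(fit.params["W"])
    return {"mae": float(np.mean(errors)), "mae_by_level": by_level,
            "goal_data_min_W": float(np.min(goal_ws)),
            "n_trials": len(bases[0])}


# ---------------------------------------------------------------------------
# approach/avoid planning patterns and model comparison
# ---------------------------------------------------------------------------

def planning_pattern_study(n_envs: int = 3, n_seeds: int = 10,
                           n_simulations: int = 200,
                           fit_n_simulations: int = 200,
                           n_fit_seeds: int = 4, ibs_repeats: int = 2,
                           theta: float = 1.0, seed: int = 0) -> dict:
    """Rich-zone entry rates of MCTS-RW planners on approach (safe) versus
    avoid (unsafe) layouts, and mean IBS log likelihoods of the three MCTS
    variants on MCTS-RW-generated choices."""
    weights = (1.0, 0.0, 0.0)
    out = {}
    lls = {"approach": {v: [] for v in ("mcts", "mcts-rand", "mcts-rw")},
           "avoid": {v: [] for v in ("mcts", "mcts-rand", "mcts-rw")}}
    for arch in ("approach", "avoid"):
        entered = []
        for e in range(n_envs):
            env = generate_environment(EnvironmentSpec(
                archetype=arch, moves_per_turn_prey=4,
                moves_per_turn_predator=6, n_turns=2, seed=seed * 613 + e))
            problem = PlanningProblem(env, weights)
            for s in range(n_seeds):
                rec = simulate_planner_game(
                    env, weights,
                    PlannerParams(variant="mcts-rw", theta=theta,
                                  n_simulations=n_simulations),
                    seed=seed * 131071 + 17 * e + s, problem=problem)
                entered.append(any(p in env.rich_zone
                                   for p in rec.prey_positions))
                if s < n_fit_seeds:
                    for cand in ("mcts", "mcts-rand", "mcts-rw"):
                        est = planner_ibs_loglik(
                            rec.choices, problem, cand, theta=theta,
                            n_simulations=fit_n_simulations,
                            repeats=ibs_repeats, K_max=15,
                            seed=seed + 100 * e + s)
                        lls[arch][cand].append(est.loglik)
        out[f"entry_rate_{arch}"] = float(np.mean(entered))
    for arch in lls:
        for cand, v in lls[arch].items():
            out[f"ibs_{arch}_{cand}"] = float(np.mean(v))
    return out


# ---------------------------------------------------------------------------
# IBS calibration
# ---------------------------------------------------------------------------

def ibs_bernoulli_study(p: float = 0.3, n_trials: int = 200,
                        repeats: int = 16, seed: int = 0) -> dict:
    """IBS estimate versus the exact log likelihood on a Bernoulli toy where
    the observed response is always emitted with probability ``p``."""

    def model(context, rng: random.Random) -> str:
        return "yes" if rng.random() < p else "no"

    data = [(t, "yes") for t in range(n_trials)]
    vals = [ibs_loglik(model, data, K_max=5000, repeats=1,
                       seed=seed + 71 * r).loglik for r in range(repeats)]
    exact = n_trials * math.log(p)
    estimate = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(repeats))
    z = (estimate - exact) / se if se > 0 else 0.0
    return {"estimate": estimate, "exact": exact, "se": se,
            "z": float(z), "n_trials": n_trials, "repeats": repeats}


def ibs_harmonic_contribution(K: int = 4) -> float:
    """IBS contribution of a single trial whose first match occurs on draw K
    (computed by running the estimator on a deterministic counter model)."""
    calls = {"n": 0}

    def model(context, rng: random.Random) -> str:
        calls["n"] += 1
        return "match" if calls["n"] % K == 0 else "miss"

    est = ibs_loglik(model, [(0, "match")], K_max=1000, repeats=1, seed=0)
    return est.loglik


# ---------------------------------------------------------------------------
# threat-sensitivity dose-response
# ---------------------------------------------------------------------------

def theta_monotonicity_study(thetas: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
                             n_seeds: int = 60, n_simulations: int = 400,
                             tau_opp: float = THREAT_STUDY_TAU_OPP,
                             n_envs: int = 6, seed: int = 0) -> dict:
    """Mean prey steps in the rich zone as a function of threat sensitivity
    on safe (approach) short-horizon layouts.

    Runs are pooled over ``n_envs`` layout draws so single-layout
    idiosyncrasies do not dominate the dose-response.
    """
    envs = [generate_environment(exp3_env_spec("short_predictable",
                                               seed=seed * 211 + k))
            for k in range(n_envs)]
    problems = [PlanningProblem(env, (1.0, 0.0, 0.0)) for env in envs]
    means = {}
    for theta in thetas:
        occ = []
        for s in range(n_seeds):
            env = envs[s % n_envs]
            rec = simulate_planner_game(
                env, (1.0, 0.0, 0.0),
                PlannerParams(variant="mcts-rw", tau_opp=tau_opp,
                              theta=theta, n_simulations=n_simulations),
                seed=seed * 4099 + s, problem=problems[s % n_envs])
            occ.append(rec.rich_zone_steps)
        means[theta] = float(np.mean(occ))
    vals = [means[t] for t in thetas]
    return {"mean_rich_steps": means,
            "monotone_nonincreasing": all(a >= b for a, b in
                                          zip(vals, vals[1:])),
            "n_seeds": n_seeds}
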