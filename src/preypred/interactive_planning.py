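"""Prey-side interactive planning: joint-state MDP, MCTS/UCT variants, IBS
likelihoods, and simulation-based parameter estimation.

The prey plans in an interactive MDP whose state is the joint (prey, predator)
position -- 210² = 44,100 position states on the wall-free default grid --
which is approximated online with Monte Carlo tree search (UCT).  Three
variants differ only in how simulated predator moves are generated:

- ``mcts``      : the predator is absent from simulations (non-interactive).
- ``mcts-rand`` : predator moves are uniform random over legal moves.
- ``mcts-rw``   : predator moves follow its value-iteration policy under the
                  true reward weights (max rule, or softmax with temperature
                  ``tau_opp > 0``).

Simulated returns are 100 per coin collected minus ``1000 * theta`` on
capture (``theta`` is the planner's threat sensitivity); simulations run to
the end of the game.  Returns are min-max normalized within each search tree
so a single exploration constant (default sqrt(2)) is serviceable across
``theta``.  Children are keyed by the prey's action only, so node statistics
average over opponent stochasticity (open-loop backups).

Because action selection is itself stochastic, model likelihoods are estimated
by inverse binomial sampling (IBS): simulate the model until it reproduces the
observed choice; a first match on draw K contributes -sum_{j<K} 1/j.
"""

from __future__ import annotations

import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from itertools import accumulate
from typing import Callable, Sequence

import numpy as np

from .hexworld import (DIR_INDEX, DIRECTIONS, Environment, HexCell,
                       N_FEATURES)
from .hexworld import build_mdp
from .predator_agent import ActionRule, value_iteration

VARIANTS = ("mcts", "mcts-rand", "mcts-rw")


@dataclass(frozen=True)
class JointState:
    """A prey decision point in the joint prey-predator MDP.

    ``moves_left_in_turn`` counts prey moves still to make this turn
    (including the upcoming one); ``turns_left`` includes the current turn.
    """

    prey: HexCell
    predator: HexCell
    coins_remaining: frozenset[HexCell]
    whose_move: str = "prey"
    moves_left_in_turn: int = 1
    turns_left: int = 1


@dataclass
class PlannerParams:
    variant: str = "mcts-rw"
    tau_opp: float = 0.0            # 0 = max-rule opponent model
    theta: float = 1.0              # multiplies the 1000-point capture cost
    exploration_c: float = math.sqrt(2.0)
    n_simulations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.tau_opp < 0 or self.theta < 0:
            raise ValueError("tau_opp and theta must be >= 0")
        if self.exploration_c <= 0:
            raise ValueError("exploration constant must be positive")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")


def joint_state_count(env: Environment) -> int:
    """Number of joint (prey, predator) position states."""
    return len(env.cells()) ** 2


class PlanningProblem:
    """Precomputed move tables for fast game simulation on one environment."""

    def __init__(self, env: Environment, weights: Sequence[float],
                 discount: float = 0.9):
        self.env = env
        self.weights = np.asarray(weights, dtype=float)
        self.discount = discount
        mdp = build_mdp(env, np.zeros(N_FEATURES), env.prey_start, discount)
        self.mdp = mdp
        self.states = mdp.states
        self.index = mdp.index
        S = mdp.n_states
        self.adj_next: list[list[int]] = []
        self.adj_dirs: list[list[str]] = []
        for s in range(S):
            nxt, dirs = [], []
            for a in range(6):
                if mdp.valid[s, a]:
                    nxt.append(int(mdp.transition[s, a]))
                    dirs.append(DIRECTIONS[a])
            self.adj_next.append(nxt)
            self.adj_dirs.append(dirs)
        self.coin_idx = frozenset(self.index[c] for c in env.coins)
        self.rich_idx = frozenset(self.index[c] for c in env.rich_zone)
        self._policy_cache: dict = {}

    # -- predator opponent model -----------------------------------------
    def predator_moves(self, tau: float, prey_idx: int | None = None):
        """Per-state predator move table under the reward-weight policy.

        Returns a list over predator states of either a list of greedy
        next-state candidates (``tau == 0``) or ``(next_states, cum_probs)``
        for softmax sampling.  ``prey_idx`` matters only when the predator
        values the prey feature.
        """
        prey_key = prey_idx if self.weights[2] != 0 else None
        key = (round(tau, 10), prey_key)
        if key in self._policy_cache:
            return self._policy_cache[key]
        prey_at = (self.states[prey_idx] if prey_key is not None
                   else self.env.prey_start)
        mdp = build_mdp(self.env, self.weights, prey_at, self.discount)
        values = value_iteration(mdp)
        table = []
        for s in range(mdp.n_states):
            avail = np.flatnonzero(mdp.valid[s])
            if avail.size == 0:
                table.append(([s], None) if tau > 0 else [s])
                continue
            nxt = mdp.transition[s, avail]
            q = values.Q[s, avail]
            if tau == 0:
                best = nxt[np.isclose(q, q.max())]
                table.append([int(x) for x in best])
            else:
                z = q / tau
                e = np.exp(z - z.max())
                p = e / e.sum()
                table.append(([int(x) for x in nxt],
                              list(accumulate(float(x) for x in p))))
        self._policy_cache[key] = table
        return table


def _remaining_schedule(env: Environment, state: JointState,
                        include_predator: bool) -> list[int]:
    """Remaining move sequence from ``state`` (1 = prey, 0 = predator)."""
    mpp, mpd = env.moves_per_turn_prey, env.moves_per_turn_predator
    sched = [1] * state.moves_left_in_turn
    if include_predator:
        sched += [0] * mpd
    for _ in range(state.turns_left - 1):
        sched += [1] * mpp
        if include_predator:
            sched += [0] * mpd
    return sched


class _Node:
    __slots__ = ("visits", "total", "children")

    def __init__(self):
        self.visits = 0
        self.total = 0.0
        self.children: dict[int, "_Node"] = {}


def mcts_choose(state: JointState, problem: PlanningProblem,
                params: PlannerParams,
                rng: random.Random | None = None,
                return_stats: bool = False):
    """Run UCT from ``state`` and return the prey direction with most visits.

    With ``return_stats`` also returns ``{direction: visit count}`` at the
    root.
    """
    if state.whose_move != "prey":
        raise ValueError("mcts_choose plans prey moves only")
    rng = rng if rng is not None else random.Random(params.seed)
    env = problem.env
    adj_next = problem.adj_next
    coin_idx = problem.coin_idx
    capture_cost = 1000.0 * params.theta
    interactive = params.variant != "mcts"
    sched = _remaining_schedule(env, state, include_predator=interactive)
    prey0 = problem.index[state.prey]
    pred0 = problem.index[state.predator]
    collected0 = frozenset(problem.index[c] for c in env.coins
                           if c not in state.coins_remaining)
    opp_table = None
    if params.variant == "mcts-rw":
        opp_table = problem.predator_moves(params.tau_opp, prey0)
    legal0 = adj_next[prey0]
    if not legal0:
        raise ValueError("prey has no legal move")

    def predator_step(pred: int, rnd: random.Random) -> int:
        if params.variant == "mcts-rand":
            nxt = adj_next[pred]
            return nxt[rnd.randrange(len(nxt))] if nxt else pred
        entry = opp_table[pred]
        if params.tau_opp == 0:
            return entry[rnd.randrange(len(entry))] if len(entry) > 1 else entry[0]
        nxt, cum = entry
        return nxt[bisect_right(cum, rnd.random() * cum[-1])] if cum else nxt[0]

    root = _Node()
    ret_min, ret_max = math.inf, -math.inf
    c = params.exploration_c

    for _ in range(params.n_simulations):
        node = root
        path = [root]
        prey, pred = prey0, pred0
        collected = None  # lazily copied
        reward = 0.0
        pos = 0
        terminal = False
        rollout = False
        # selection / expansion (tree nodes sit at prey decision points)
        while not terminal:
            legal = adj_next[prey]
            if not legal:
                break
            unexpanded = [a for a in legal if a not in node.children]
            if unexpanded:
                a = unexpanded[rng.randrange(len(unexpanded))]
                child = _Node()
                node.children[a] = child
                path.append(child)
                rollout = True
            else:
                best, best_u = None, -math.inf
                log_n = math.log(node.visits) if node.visits > 0 else 0.0
                span = (ret_max - ret_min) or 1.0
                for a2, ch in node.children.items():
                    q = ((ch.total / ch.visits) - ret_min) / span
                    u = q + c * math.sqrt(log_n / ch.visits)
                    if u > best_u:
                        best, best_u = a2, u
                a = best
                child = node.children[a]
                path.append(child)
            # apply the prey move
            prey = a
            if prey in coin_idx:
                if collected is None:
                    collected = set(collected0)
                if prey not in collected:
                    collected.add(prey)
                    reward += 100.0
            if interactive and prey == pred:
                reward -= capture_cost
                terminal = True
                break
            pos += 1
            # advance predator moves until the next prey decision or game end
            while pos < len(sched) and sched[pos] == 0:
                pred = predator_step(pred, rng)
                if pred == prey:
                    reward -= capture_cost
                    terminal = True
                    break
                pos += 1
            if terminal or pos >= len(sched):
                break
            node = child
            if rollout:
                break
        # rollout with a uniform prey policy
        if rollout and not terminal:
            while pos < len(sched):
                if sched[pos] == 1:
                    legal = adj_next[prey]
                    if not legal:
                        break
                    prey = legal[rng.randrange(len(legal))]
                    if prey in coin_idx:
                        if collected is None:
                            collected = set(collected0)
                        if prey not in collected:
                            collected.add(prey)
                            reward += 100.0
                    if interactive and prey == pred:
                        reward -= capture_cost
                        break
                else:
                    pred = predator_step(pred, rng)
                    if pred == prey:
                        reward -= capture_cost
                        break
                pos += 1
        if reward < ret_min:
            ret_min = reward
        if reward > ret_max:
            ret_max = reward
        for nd in path:
            nd.visits += 1
            nd.total += reward
    # most-visited root action
    best_a = max(root.children.items(), key=lambda kv: kv[1].visits)[0]
    s0 = problem.index[state.prey]
    choice = problem.adj_dirs[s0][problem.adj_next[s0].index(best_a)]
    if return_stats:
        stats = {problem.adj_dirs[s0][problem.adj_next[s0].index(a)]: ch.visits
                 for a, ch in root.children.items()}
        return choice, stats
    return choice


# ---------------------------------------------------------------------------
# full-game simulation
# ---------------------------------------------------------------------------

@dataclass
class GameRecord:
    choices: list[tuple[JointState, str]]
    prey_positions: list[HexCell]
    predator_positions: list[HexCell]
    points: int
    captured: bool
    coins_collected: int
    rich_zone_steps: int


def simulate_planner_game(env: Environment, weights, params: PlannerParams,
                          predator_rule: ActionRule | None = None,
                          seed: int = 0,
                          problem: PlanningProblem | None = None) -> GameRecord:
    """Play one full game: the prey plans each move with MCTS; the real
    predator follows its value-iteration policy under ``predator_rule``."""
    rng = random.Random(seed)
    problem = problem if problem is not None else PlanningProblem(env, weights)
    predator_rule = predator_rule or ActionRule("max")
    tau_real = predator_rule.temperature if predator_rule.kind == "softmax" else 0.0
    prey, pred = env.prey_start, env.predator_start
    coins = set(env.coins)
    points = 0
    captured = False
    choices: list[tuple[JointState, str]] = []
    prey_pos: list[HexCell] = []
    pred_pos: list[HexCell] = []
    rich_steps = 0
    collected = 0
    for turn in range(env.n_turns):
        turns_left = env.n_turns - turn
        for m in range(env.moves_per_turn_prey):
            state = JointState(prey=prey, predator=pred,
                               coins_remaining=frozenset(coins),
                               whose_move="prey",
                               moves_left_in_turn=env.moves_per_turn_prey - m,
                               turns_left=turns_left)
            action = mcts_choose(state, problem, params,
                                 random.Random(rng.getrandbits(31)))
            choices.append((state, action))
            s = problem.index[prey]
            prey = problem.states[problem.adj_next[s][
                problem.adj_dirs[s].index(action)]]
            prey_pos.append(prey)
            if prey in env.rich_zone:
                rich_steps += 1
            if prey in coins:
                coins.discard(prey)
                points += 100
                collected += 1
            if prey == pred:
                captured = True
                points -= 1000
                break
        if captured:
            break
        table = problem.predator_moves(tau_real, problem.index[prey])
        for _ in range(env.moves_per_turn_predator):
            p = problem.index[pred]
            entry = table[p]
            if tau_real == 0:
                nxt = entry[rng.randrange(len(entry))] if len(entry) > 1 else entry[0]
            else:
                cand, cum = entry
                nxt = cand[bisect_right(cum, rng.random() * cum[-1])] if cum else cand[0]
            pred = problem.states[nxt]
            pred_pos.append(pred)
            if pred == prey:
                captured = True
                points -= 1000
                break
        if captured:
            break
    return GameRecord(choices=choices, prey_positions=prey_pos,
                      predator_positions=pred_pos, points=points,
                      captured=captured, coins_collected=collected,
                      rich_zone_steps=rich_steps)


# ---------------------------------------------------------------------------
# inverse binomial sampling
# ---------------------------------------------------------------------------

@dataclass
class IBSEstimate:
    loglik: float
    per_trial_K: list[int]
    repeats: int
    capped: bool = False


def _harmonic(k: int) -> float:
    return sum(1.0 / j for j in range(1, k))


def ibs_loglik(model: Callable[[object, random.Random], str],
               data: Sequence[tuple[object, str]], K_max: int = 2500,
               repeats: int = 16, seed: int = 0) -> IBSEstimate:
    """Unbiased IBS estimate of the summed log likelihood of observed choices.

    ``model(context, rng)`` draws one simulated choice for a trial's context.
    For each trial the model is simulated until it first reproduces the
    observed choice on draw K; that trial contributes -sum_{j=1}^{K-1} 1/j.
    Estimates are averaged over ``repeats`` independent runs.  Trials reaching
    ``K_max`` are floored at the K_max harmonic penalty and flagged.
    """
    if repeats < 1 or K_max < 1:
        raise ValueError("repeats and K_max must be >= 1")
    master = random.Random(seed)
    totals = []
    mean_K = [0.0] * len(data)
    capped = False
    for _ in range(repeats):
        total = 0.0
        for i, (context, observed) in enumerate(data):
            k = 1
            while k <= K_max:
                sim = model(context, random.Random(master.getrandbits(31)))
                if sim == observed:
                    break
                k += 1
            if k > K_max:
                k = K_max
                capped = True
            total -= _harmonic(k)
            mean_K[i] += k / repeats
        totals.append(total)
    return IBSEstimate(loglik=float(np.mean(totals)),
                       per_trial_K=[int(round(k)) for k in mean_K],
                       repeats=repeats, capped=capped)


def planner_ibs_loglik(choices: Sequence[tuple[JointState, str]],
                       problem: PlanningProblem, variant: str,
                       tau_opp: float = 0.0, theta: float = 1.0,
                       n_simulations: int = 200, K_max: int = 25,
                       repeats: int = 1, seed: int = 0) -> IBSEstimate:
    """IBS log likelihood of observed prey choices under one MCTS variant."""
    params = PlannerParams(variant=variant, tau_opp=tau_opp, theta=theta,
                           n_simulations=n_simulations)

    def model(context: JointState, rng: random.Random) -> str:
        return mcts_choose(context, problem, params, rng)

    return ibs_loglik(model, choices, K_max=K_max, repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# parameter estimation (grid search / rejection sampling)
# ---------------------------------------------------------------------------

@dataclass
class PlannerParamEstimate:
    tau_opp: float
    theta: float
    tau_spread: float = 0.0
    theta_spread: float = 0.0
    method: str = "grid"
    n_accepted: int = 0
    flagged: bool = False


def estimate_planner_params(choices: Sequence[tuple[JointState, str]],
                            problem: PlanningProblem, method: str = "grid",
                            tau_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 3.0),
                            theta_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
                            n_simulations: int = 200, repeats: int = 1,
                            K_max: int = 25, budget: int = 200,
                            summary_target: dict | None = None,
                            seed: int = 0) -> PlannerParamEstimate:
    """Estimate the MCTS-RW opponent temperature and threat sensitivity.

    ``grid``: IBS log likelihood on a (tau, theta) lattice, argmax returned.
    ``rejection``: simulate ``budget`` uniform parameter draws, score them by
    per-choice agreement with the observed actions, and return the mean and
    spread of the best-matching tenth.
    """
    if method == "grid":
        best, best_ll = None, -math.inf
        for i, tau in enumerate(tau_grid):
            for j, theta in enumerate(theta_grid):
                est = planner_ibs_loglik(choices, problem, "mcts-rw",
                                         tau_opp=tau, theta=theta,
                                         n_simulations=n_simulations,
                                         K_max=K_max, repeats=repeats,
                                         seed=seed + 97 * i + j)
                if est.loglik > best_ll:
                    best, best_ll = (tau, theta), est.loglik
        return PlannerParamEstimate(tau_opp=best[0], theta=best[1],
                                    method="grid")
    if method != "rejection":
        raise ValueError("method must be 'grid' or 'rejection'")
    rng = random.Random(seed)
    tau_hi = max(tau_grid)
    theta_hi = max(theta_grid)
    draws = []
    for b in range(budget):
        tau = rng.uniform(0.0, tau_hi)
        theta = rng.uniform(0.0, theta_hi)
        params = PlannerParams(variant="mcts-rw", tau_opp=tau, theta=theta,
                               n_simulations=n_simulations)
        agree = 0
        for context, observed in choices:
            sim = mcts_choose(context, problem, params,
                              random.Random(rng.getrandbits(31)))
            agree += sim == observed
        draws.append((agree, tau, theta))
    draws.sort(key=lambda t: -t[0])
    keep = draws[:max(1, budget // 10)]
    taus = [t for _, t, _ in keep]
    thetas = [t for _, _, t in keep]
    return PlannerParamEstimate(tau_opp=float(np.mean(taus)),
                                theta=float(np.mean(thetas)),
                                tau_spread=float(np.std(taus)),
                                theta_spread=float(np.std(thetas)),
                                method="rejection", n_accepted=len(keep),
                                flagged=len(keep) == 0)
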