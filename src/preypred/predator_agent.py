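"""The ground-truth threatening agent.

The predator plans by value iteration over the feature MDP (discount 0.9,
at most 500 sweeps), assuming the prey stays still, and picks actions either
greedily ("max" rule, seeded uniform tie-breaking) or by a softmax over Q
values.  During a multi-turn game the MDP is rebuilt and re-solved at the
start of each predator turn so the prey feature tracks the prey's movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hexworld import (DIRECTIONS, N_DIRECTIONS, Environment, FeatureMDP,
                       HexCell, Trajectory, TrajectoryStep, build_mdp)

VI_MAX_ITERS = 500
VI_TOL = 1e-6


@dataclass
class ValueTable:
    """State values and action values from value iteration.

    ``Q`` is ``(S, 6)`` with ``-inf`` on unavailable actions; states with no
    available action keep value 0.
    """

    V: np.ndarray
    Q: np.ndarray
    iterations_run: int
    mdp: FeatureMDP


@dataclass(frozen=True)
class ActionRule:
    """Greedy ("max") or softmax action selection; τ is the softmax temperature
    (fixed at 1 in the stochastic-agent conditions)."""

    kind: str = "max"
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("max", "softmax"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "softmax" and not (np.isfinite(self.temperature)
                                           and self.temperature > 0):
            raise ValueError("softmax temperature must be finite and positive")


def value_iteration(mdp: FeatureMDP, max_iters: int = VI_MAX_ITERS,
                    tol: float = VI_TOL) -> ValueTable:
    """Iterate V_{k+1}(s) = max_a [R(s,a) + γ V_k(s')] from V=0.

    Stops early once the sup-norm change falls below ``tol``.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    gamma = mdp.discount
    V = np.zeros(mdp.n_states)
    T = mdp.transition
    valid = mdp.valid
    Tc = np.where(valid, T, 0)
    neg_inf = np.full_like(mdp.reward, -np.inf)
    any_action = valid.any(axis=1)
    it = 0
    for it in range(1, max_iters + 1):
        Q = np.where(valid, mdp.reward + gamma * V[Tc], neg_inf)
        V_new = np.where(any_action, Q.max(axis=1, initial=-np.inf), 0.0)
        delta = np.max(np.abs(V_new - V))
        V = V_new
        if delta < tol:
            break
    Q = np.where(valid, mdp.reward + gamma * V[Tc], neg_inf)
    return ValueTable(V=V, Q=Q, iterations_run=it, mdp=mdp)


def softmax(x: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Numerically stable softmax; -inf entries receive zero probability."""
    z = np.asarray(x, dtype=float) / temperature
    m = np.max(z)
    e = np.exp(z - m)
    return e / e.sum()


def action_probabilities(values: ValueTable, state: HexCell,
                         rule: ActionRule) -> tuple[list[str], np.ndarray]:
    """Choice probabilities over the available actions at ``state``.

    Returns the available direction labels (canonical order) and their
    probabilities.  Under the max rule ties share probability equally.
    """
    s = values.mdp.index[state]
    avail = np.flatnonzero(values.mdp.valid[s])
    if avail.size == 0:
        raise ValueError(f"state {state} has no available actions")
    q = values.Q[s, avail]
    if rule.kind == "max":
        best = np.isclose(q, q.max())
        probs = best / best.sum()
    else:
        probs = softmax(q, rule.temperature)
    return [DIRECTIONS[a] for a in avail], probs


def choose_action(values: ValueTable, state: HexCell, rule: ActionRule,
                  rng: np.random.Generator) -> str:
    dirs, probs = action_probabilities(values, state, rule)
    return dirs[rng.choice(len(dirs), p=probs)]


def simulate_predator(env: Environment, weights: Sequence[float],
                      prey_path: Sequence[HexCell], rule: ActionRule | None = None,
                      seed: int = 0, moves_per_turn: int | None = None,
                      discount: float = 0.9, start: HexCell | None = None,
                      max_iters: int = VI_MAX_ITERS) -> Trajectory:
    """Simulate the predator over ``len(prey_path)`` turns.

    ``prey_path[i]`` is where the prey sits during predator turn ``i``.  At the
    start of each turn the MDP is rebuilt with the prey at that cell and
    re-solved; the predator then takes ``moves_per_turn`` moves under ``rule``.
    """
    rule = rule or ActionRule("max")
    mpt = moves_per_turn if moves_per_turn is not None else env.moves_per_turn_predator
    rng = np.random.default_rng(seed)
    pos = start if start is not None else env.predator_start
    steps: list[TrajectoryStep] = []
    values: ValueTable | None = None
    last_prey: HexCell | None = None
    for prey_at in prey_path:
        prey_at = HexCell(*prey_at)
        if values is None or prey_at != last_prey:
            mdp = build_mdp(env, weights, prey_at, discount)
            values = value_iteration(mdp, max_iters=max_iters)
            last_prey = prey_at
        for _ in range(mpt):
            action = choose_action(values, pos, rule, rng)
            nxt = values.mdp.states[values.mdp.transition[
                values.mdp.index[pos], DIRECTIONS.index(action)]]
            steps.append(TrajectoryStep(actor="predator", state=pos,
                                        action=action, next_state=nxt,
                                        prey_at=prey_at))
            pos = nxt
    return Trajectory(steps=steps)
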