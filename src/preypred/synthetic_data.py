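"""Generators of environments and simulated participants for all three studies.

Environment archetypes reproduce the defining constraints of the task layouts
rather than any literal map:

- ``decoupled`` : the predator's route to its preferred trees crosses red
                  ground, decoupling feature occupancy from preference.
- ``approach``  : a rich coin cluster lies OFF the predator's greedy route to
                  the trees (safe in fact, though close enough to its side
                  that opponent models expecting straying perceive risk),
                  with sparse coins on the far side.
- ``avoid``     : the rich coins sit in a walled corridor whose passage is
                  blocked by the camping predator (reachable only through
                  its cycle).
- ``practice`` / ``random`` : open layouts with separated feature clusters
                  and scattered singleton patches.

``approach``/``avoid`` layouts are verified by simulating a tree-preferring
max-rule predator and checking whether its path intersects the rich zone;
generation retries with jittered feature placements until the check passes.

Simulated observers (experiment-1 style) predict predator moves from the
W-weighted combination of goal inference and policy learning, rate their
confidence from a Beta model that improves over trials, and report reward
weights as the calibrated truth plus Gaussian noise rounded to the 9-point
scale.  Simulated planners (experiments 2-3) choose moves with an MCTS
variant.  All randomness is seed-driven and bundles serialize to the
canonical CSV schemas the fitting modules read.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .action_prediction import (LearnerParams, PolicyEstimate,
                                build_prediction_dataset, combine_predictions,
                                update_policy)
from .hexworld import (DIR_INDEX, DIRECTIONS, Environment, HexCell,
                       Trajectory, TrajectoryStep, neighbors, offset_neighbor,
                       trajectory_to_frame)
from .interactive_planning import (GameRecord, JointState, PlannerParams,
                                   PlanningProblem, simulate_planner_game)
from .predator_agent import ActionRule, simulate_predator
from .reward_inference import calibrate

ARCHETYPES = ("decoupled", "approach", "avoid", "practice", "random")

CONDITION_WEIGHTS = {"A": (1.0, 0.0, 0.0),     # trees
                     "B": (0.0, 1.0, 0.0),     # red ground
                     "C": (0.0, 0.0, 1.0)}     # prey


@dataclass
class EnvironmentSpec:
    archetype: str = "random"
    width: int = 21
    height: int = 10
    wall_density: float = 0.0
    moves_per_turn_prey: int = 1
    moves_per_turn_predator: int = 2
    n_turns: int = 10
    seed: int = 0
    max_retries: int = 30
    #: horizontal placement of the predator start in approach/avoid layouts;
    #: near the trees (0.8) makes it camp early, mid-grid values leave it
    #: within striking range of the rich zone during early turns
    predator_col_frac: float = 0.8
    #: approach-layout flavor: "camp" puts the trees just beyond the predator
    #: (it settles quickly; the zone sits beneath its start), "transit" puts
    #: the trees far across the map so the predator sweeps a long route past
    #: the zone -- noisy opponent models then see real exposure
    approach_layout: str = "camp"

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not 0 <= self.wall_density < 0.5:
            raise ValueError("wall density must lie in [0, 0.5)")


@dataclass
class SimulatedSubjectSpec:
    role: str = "predictor"            # "predictor" or "planner"
    W: float = 0.87
    alpha: float = 0.5
    lam: float = 0.5
    rating_noise_sd: float = 1.0
    variant: str = "mcts-rw"
    tau_opp: float = 0.0
    theta: float = 1.0
    n_simulations: int = 300
    n_games: int = 6
    seed: int = 0


def _connected(env_cells: set[HexCell], width: int, height: int) -> bool:
    if not env_cells:
        return False
    walls = {HexCell(c, r) for c in range(width) for r in range(height)} - env_cells
    probe = Environment(width=width, height=height, walls=frozenset(walls),
                        predator_start=min(env_cells),
                        prey_start=max(env_cells))
    start = next(iter(env_cells))
    seen = {start}
    queue = deque([start])
    while queue:
        cell = queue.popleft()
        for _, nxt in neighbors(probe, cell):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen == env_cells


def _cluster(center: HexCell, size: int, cells: set[HexCell],
             env: Environment) -> frozenset[HexCell]:
    """A connected blob of ``size`` cells grown from ``center``."""
    blob = {center}
    frontier = deque([center])
    while len(blob) < size and frontier:
        cell = frontier.popleft()
        for _, nxt in neighbors(env, cell):
            if nxt in cells and nxt not in blob:
                blob.add(nxt)
                frontier.append(nxt)
                if len(blob) >= size:
                    break
    return frozenset(blob)


def generate_environment(spec: EnvironmentSpec) -> Environment:
    """Generate one environment satisfying its archetype's constraints."""
    last_error = None
    for attempt in range(spec.max_retries):
        rng = random.Random((spec.seed, attempt).__hash__() & 0x7FFFFFFF)
        try:
            env = _generate_once(spec, rng)
        except ValueError as exc:          # degenerate draw; retry
            last_error = exc
            continue
        if spec.archetype not in ("approach", "avoid"):
            return env
        if _route_check(env) == (spec.archetype == "avoid"):
            return env
        last_error = ValueError("route/zone constraint not met")
    raise RuntimeError(
        f"could not generate a valid {spec.archetype!r} environment after "
        f"{spec.max_retries} attempts: {last_error}")


def _route_check(env: Environment) -> bool:
    """True if a tree-preferring max-rule predator's route enters the rich zone."""
    total_turns = env.n_turns
    traj = simulate_predator(env, (1.0, 0.0, 0.0),
                             [env.prey_start] * total_turns,
                             ActionRule("max"), seed=0)
    visited = {env.predator_start} | {s.next_state for s in traj.steps}
    return bool(visited & env.rich_zone)


def _generate_once(spec: EnvironmentSpec, rng: random.Random) -> Environment:
    W, H = spec.width, spec.height
    all_cells = {HexCell(c, r) for c in range(W) for r in range(H)}
    walls: set[HexCell] = set()
    if spec.wall_density > 0:
        n_walls = int(spec.wall_density * W * H)
        walls = set(rng.sample(sorted(all_cells), n_walls))
        if not _connected(all_cells - walls, W, H):
            raise ValueError("walls disconnect the grid")
    cells = all_cells - walls
    base = Environment(width=W, height=H, walls=frozenset(walls),
                       predator_start=min(cells), prey_start=max(cells))

    def free(cell: HexCell) -> bool:
        return cell in cells

    def pick(col_lo, col_hi, row_lo, row_hi) -> HexCell:
        for _ in range(200):
            cell = HexCell(rng.randint(col_lo, col_hi), rng.randint(row_lo, row_hi))
            if free(cell):
                return cell
        raise ValueError("no free cell in region")

    if spec.archetype == "avoid":
        # Unsafe layout: the rich coins sit in a one-cell-wide walled
        # corridor whose only passage is blocked by the tree pair where the
        # predator camps -- the coins cannot be reached without stepping
        # into the predator's cycle.
        if W < 15 or H < 7:
            raise ValueError("avoid corridor needs at least a 15 x 7 grid")
        r = H // 2 + rng.randint(-1, 0)
        c_mouth = int(W * 0.45) + rng.randint(-1, 1)
        c_camp = c_mouth + 1                     # camp right behind the mouth
        c_end = c_camp + 5
        if c_end + 1 >= W:
            raise ValueError("corridor does not fit")
        walls = set()
        for c in range(c_mouth - 1, c_end + 2):
            walls.add(HexCell(c, r - 1))
            walls.add(HexCell(c, r + 1))
        walls.add(HexCell(c_end + 1, r))
        walls = {w for w in walls if 0 <= w.col < W and 0 <= w.row < H}
        cells = all_cells - walls
        trees = frozenset({HexCell(c_camp, r), HexCell(c_camp + 1, r)})
        zone = frozenset(HexCell(c, r) for c in range(c_camp, c_end + 1))
        pred_start = HexCell(c_end - 1, r)
        sparse = set()
        for frac, row in ((0.12, H - 2), (0.25, H - 1), (0.1, 1)):
            cand = HexCell(int(W * frac) + rng.randint(0, 1),
                           max(row - rng.randint(0, 1), 0))
            if cand in cells:
                sparse.add(cand)
        if not sparse:
            raise ValueError("no sparse coins placed")
        # a lure coin at the corridor mouth: safe for everyone, but it leads
        # short-sighted planners to discover the guarded corridor behind it
        sparse.add(HexCell(c_mouth, r))
        # the prey starts on the corridor axis, a few cells out, so the
        # guarded rich corridor and the sparse coins are both in plain view
        prey_start = HexCell(c_mouth - 3 + rng.randint(-1, 0), r)
        if prey_start not in cells or prey_start in sparse:
            raise ValueError("prey start blocked")
        red = _cluster(HexCell(2, 1), 3,
                       cells - trees - zone - sparse - {pred_start, prey_start},
                       Environment(width=W, height=H, walls=frozenset(walls),
                                   predator_start=min(cells),
                                   prey_start=max(cells)))
        return Environment(
            width=W, height=H, walls=frozenset(walls), trees=trees,
            red_ground=red, coins=frozenset(zone | sparse),
            predator_start=pred_start, prey_start=prey_start,
            rich_zone=zone,
            moves_per_turn_prey=spec.moves_per_turn_prey,
            moves_per_turn_predator=spec.moves_per_turn_predator,
            n_turns=spec.n_turns)

    if spec.archetype == "approach":
        # Safe layout: the trees sit beyond the predator's start, so its
        # greedy route leads away from the rich coins beneath it.  The zone
        # is near enough to the predator's side that an opponent model which
        # expects random straying perceives risk there, while the true
        # (goal-directed) route never comes close.
        frac = spec.predator_col_frac
        pred_start = pick(int(W * max(frac - 0.04, 0.0)),
                          int(W * min(frac + 0.04, 0.95)), 1, 3)
        if spec.approach_layout == "camp":
            tree_c = HexCell(min(pred_start.col + 3 + rng.randint(0, 1), W - 2),
                             max(pred_start.row - 1, 0))
            # rich zone a few cells beneath the predator's start
            zone_c = HexCell(max(pred_start.col - 2 + rng.randint(-1, 0), 0),
                             min(pred_start.row + 3 + rng.randint(0, 1), H - 2))
        elif spec.approach_layout == "transit":
            tree_c = HexCell(int(W * 0.67) + rng.randint(-1, 1),
                             int(H * 0.4) + rng.randint(-1, 1))
            # rich zone close beneath the early leg of the predator's long
            # route: the greedy sweep passes it by, but any assumed straying
            # exposes a visiting prey
            zone_c = HexCell(min(pred_start.col + 1 + rng.randint(0, 1), W - 2),
                             min(pred_start.row + 2 + rng.randint(0, 1), H - 2))
        else:
            raise ValueError(f"unknown approach layout {spec.approach_layout!r}")
        if not free(tree_c):
            raise ValueError("tree center blocked")
        trees = _cluster(tree_c, 4, cells - {pred_start}, base)
        if not free(zone_c):
            raise ValueError("zone center blocked")
        zone = _cluster(zone_c, 6, cells - trees - {pred_start}, base)
        sparse = set()
        for frac, row in ((0.12, H - 2), (0.28, H - 1), (0.42, H - 2)):
            try:
                sparse.add(pick(max(int(W * frac) - 1, 0), int(W * frac) + 1,
                                max(row - 1, 0), row))
            except ValueError:
                pass
        sparse -= set(zone) | set(trees) | {pred_start}
        if not sparse:
            raise ValueError("no sparse coins placed")
        # prey starts equidistant between the rich zone and the sparse coins,
        # a few moves from each, so the approach/avoid trade-off is real
        zone_d = {c: min(hex_distance(c, z) for z in zone) for c in cells}
        sparse_d = {c: min(hex_distance(c, sp) for sp in sparse) for c in cells}
        candidates = [c for c in cells
                      if 3 <= zone_d[c] <= 4
                      and zone_d[c] <= sparse_d[c] <= zone_d[c] + 2
                      and hex_distance(c, pred_start) >= 5
                      and c not in zone and c not in trees and c not in sparse
                      and c != pred_start]
        if not candidates:
            raise ValueError("no equidistant prey start")
        prey_start = sorted(candidates)[rng.randrange(len(candidates))]
        red = _cluster(pick(1, 3, 1, 2), 3,
                       cells - trees - zone - {pred_start, prey_start}, base)
        return Environment(
            width=W, height=H, walls=frozenset(walls), trees=trees,
            red_ground=red, coins=frozenset(zone | sparse),
            predator_start=pred_start, prey_start=prey_start,
            rich_zone=frozenset(zone),
            moves_per_turn_prey=spec.moves_per_turn_prey,
            moves_per_turn_predator=spec.moves_per_turn_predator,
            n_turns=spec.n_turns)

    if spec.archetype == "decoupled":
        pred_start = pick(0, 1, 1, H - 2)
        trees = _cluster(pick(W - 3, W - 2, 1, H - 2), 4, cells, base)
        # red band across the predator's straight route to the trees
        red = set()
        for c in range(2, W - 4, 2):
            cell = HexCell(c, pred_start.row + rng.randint(-1, 1))
            if free(cell) and cell not in trees:
                red.add(cell)
        prey_start = pick(W // 2 - 2, W // 2 + 2, H - 3, H - 1)
        coins = {pick(2, W - 3, 0, H - 1) for _ in range(5)}
        coins -= trees | red | {pred_start, prey_start}
        if prey_start == pred_start:
            raise ValueError("start collision")
        return Environment(
            width=W, height=H, walls=frozenset(walls), trees=trees,
            red_ground=frozenset(red), coins=frozenset(coins),
            predator_start=pred_start, prey_start=prey_start,
            moves_per_turn_prey=spec.moves_per_turn_prey,
            moves_per_turn_predator=spec.moves_per_turn_predator,
            n_turns=spec.n_turns)

    # practice / random: one main cluster per feature, kept apart so
    # trajectories carry usable evidence, plus scattered singleton patches
    # across the map (as in the designed task maps)
    trees = _cluster(pick(0, W - 1, 0, H - 1), rng.randint(3, 5), cells, base)
    red = None
    for _ in range(50):
        center = pick(0, W - 1, 0, H - 1)
        if min(hex_distance(center, t) for t in trees) >= 7:
            red = _cluster(center, rng.randint(3, 5), cells - trees, base)
            if min(hex_distance(r, t) for r in red for t in trees) >= 5:
                break
            red = None
    if red is None:
        raise ValueError("could not separate feature clusters")
    trees, red = set(trees), set(red)
    for _ in range(3):
        cand = pick(0, W - 1, 0, H - 1)
        if min(hex_distance(cand, r) for r in red) >= 4:
            trees.add(cand)
        cand = pick(0, W - 1, 0, H - 1)
        if cand not in trees and min(hex_distance(cand, t) for t in trees) >= 4:
            red.add(cand)
    trees, red = frozenset(trees), frozenset(red)
    features = trees | red
    pred_start = None
    for _ in range(100):
        cand = pick(0, W - 1, 0, H - 1)
        if min(hex_distance(cand, f) for f in features) >= 3:
            pred_start = cand
            break
    if pred_start is None:
        raise ValueError("no predator start clear of features")
    prey_start = None
    for _ in range(100):
        cand = pick(0, W - 1, 0, H - 1)
        if cand != pred_start and hex_distance(cand, pred_start) >= 4:
            prey_start = cand
            break
    if prey_start is None:
        raise ValueError("no prey start away from predator")
    coins = set()
    for _ in range(5):
        cell = pick(0, W - 1, 0, H - 1)
        if cell not in (pred_start, prey_start):
            coins.add(cell)
    return Environment(
        width=W, height=H, walls=frozenset(walls), trees=trees,
        red_ground=red, coins=frozenset(coins), predator_start=pred_start,
        prey_start=prey_start,
        moves_per_turn_prey=spec.moves_per_turn_prey,
        moves_per_turn_predator=spec.moves_per_turn_predator,
        n_turns=spec.n_turns)


# ---------------------------------------------------------------------------
# experiment 1: prediction + rating data
# ---------------------------------------------------------------------------

def random_prey_path(env: Environment, n_turns: int,
                     rng: random.Random) -> list[HexCell]:
    """Prey positions per predator turn under a uniform random walk
    (one prey move per turn)."""
    pos = env.prey_start
    path = []
    for _ in range(n_turns):
        nbrs = neighbors(env, pos)
        if nbrs:
            pos = nbrs[rng.randrange(len(nbrs))][1]
        path.append(pos)
    return path


def hex_distance(a: HexCell, b: HexCell) -> int:
    """Hex-grid distance between two cells (via cube coordinates)."""
    xa, za = a.col, a.row - (a.col - (a.col & 1)) // 2
    xb, zb = b.col, b.row - (b.col - (b.col & 1)) // 2
    ya, yb = -xa - za, -xb - zb
    return (abs(xa - xb) + abs(ya - yb) + abs(za - zb)) // 2


def simulate_chase(env: Environment, weights, n_turns: int | None = None,
                   rule: ActionRule | None = None, seed: int = 0,
                   prey_policy: str = "forage", epsilon: float = 0.15,
                   coin_weight: float = 0.5) -> tuple[Trajectory, list[HexCell]]:
    """Coupled prey-predator simulation: per turn the prey makes one move,
    then the predator takes its moves under its value-iteration policy.

    The prey emulates a participant: with ``prey_policy='forage'`` (default)
    it trades off fleeing against coin collection, scoring each neighbor by
    ``dist_to_predator - coin_weight * dist_to_nearest_coin`` (coins are
    consumed on entry); ``'avoid'`` is the pure-flight special case
    (``coin_weight=0``); ``'random'`` walks uniformly.  With probability
    ``epsilon`` the prey moves uniformly at random instead.  Returns the
    predator-step trajectory (with per-turn prey snapshots) and the prey
    path.
    """
    rule = rule or ActionRule("max")
    rng = random.Random(seed)
    n_turns = n_turns if n_turns is not None else env.n_turns
    prey = env.prey_start
    pred = env.predator_start
    coins = set(env.coins)
    cw = 0.0 if prey_policy == "avoid" else coin_weight
    steps: list[TrajectoryStep] = []
    prey_path: list[HexCell] = []
    for turn in range(n_turns):
        nbrs = neighbors(env, prey)
        if nbrs:
            if prey_policy != "random" and rng.random() >= epsilon:
                def utility(cell: HexCell) -> float:
                    u = float(hex_distance(cell, pred))
                    if cw > 0 and coins:
                        u -= cw * min(hex_distance(cell, c) for c in coins)
                    return u
                scores = [utility(n) for _, n in nbrs]
                umax = max(scores)
                best = [n for (_, n), u in zip(nbrs, scores) if u == umax]
                prey = best[rng.randrange(len(best))]
            else:
                prey = nbrs[rng.randrange(len(nbrs))][1]
        coins.discard(prey)
        prey_path.append(prey)
        turn_traj = simulate_predator(env, weights, [prey], rule,
                                      seed=rng.getrandbits(31), start=pred)
        steps.extend(turn_traj.steps)
        pred = turn_traj.steps[-1].next_state
        if pred == prey:
            break
    return Trajectory(steps=steps), prey_path


def noisy_rating(true_weights, noise_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Calibrated truth plus Gaussian noise, clipped to [-4, 4] and rounded
    to the 9-point integer scale."""
    truth = calibrate(np.asarray(true_weights, float))
    noisy = truth + rng.normal(0.0, noise_sd, size=truth.shape)
    return np.clip(np.round(noisy), -4, 4)


def simulate_prediction_subject(envs: list[Environment], condition: str,
                                subject: SimulatedSubjectSpec,
                                subject_id: str = "s0"):
    """Simulate one experiment-1 observer over ``envs``.

    Returns (per-game trajectories, predictions frame, ratings frame,
    per-game PredictionDatasets).  The observer's predictions are sampled
    from the W-weighted combined model; its policy estimate persists across
    games, as in the learning models.
    """
    weights = np.array(CONDITION_WEIGHTS[condition])
    rng = random.Random(subject.seed)
    nprng = np.random.default_rng(subject.seed + 1)
    params = LearnerParams(alpha=subject.alpha, lam=subject.lam, W=subject.W)
    est = PolicyEstimate()
    goal_cache: dict = {}
    trajectories, datasets = [], []
    pred_rows, rating_rows = [], []
    trial_counter = 0
    n_total = sum(env.n_turns * env.moves_per_turn_predator for env in envs)
    for g, env in enumerate(envs):
        cache = goal_cache if condition != "C" else {}
        traj, _ = simulate_chase(env, weights, env.n_turns, ActionRule("max"),
                                 seed=rng.getrandbits(31))
        predictions, confidences = [], []
        # goal-inference probabilities per trial (dummy predictions; reused below)
        ds_probe = build_prediction_dataset(
            env, traj, weights, [s.action for s in traj.predator_steps()],
            goal_cache=cache)
        for t, step in enumerate(traj.predator_steps()):
            probs = combine_predictions(ds_probe.goal_probs[t], est.pi,
                                        subject.W, ds_probe.avail[t])
            pred_dir = DIRECTIONS[nprng.choice(6, p=probs)]
            predictions.append(pred_dir)
            # confidence improves over the session; Beta noise around the mean
            z = trial_counter / max(n_total - 1, 1)
            m = 1.0 / (1.0 + math.exp(-(-0.5 + 2.0 * z)))
            kappa = 20.0
            conf = float(nprng.beta(max(m * kappa, 1e-3),
                                    max((1 - m) * kappa, 1e-3)))
            confidences.append(conf)
            est = update_policy(est, step.action, params, generalize=False)
            pred_rows.append({
                "subject_id": subject_id, "experiment": 1,
                "condition": condition, "game": g, "trial": t,
                "state_col": step.state.col, "state_row": step.state.row,
                "prey_col": step.prey_at.col, "prey_row": step.prey_at.row,
                "observed_action": step.action, "predicted_action": pred_dir,
                "confidence": conf,
                "correct": int(pred_dir == step.action)})
            trial_counter += 1
        ds = build_prediction_dataset(env, traj, weights, predictions,
                                      confidence=confidences, goal_cache=cache)
        datasets.append(ds)
        trajectories.append(traj)
        rating = noisy_rating(weights, subject.rating_noise_sd, nprng)
        rating_rows.append({"subject_id": subject_id, "game": g,
                            "condition": condition,
                            "rating_trees": int(rating[0]),
                            "rating_red": int(rating[1]),
                            "rating_prey": int(rating[2])})
    return trajectories, pd.DataFrame(pred_rows), pd.DataFrame(rating_rows), datasets


# ---------------------------------------------------------------------------
# experiments 2-3: planner data
# ---------------------------------------------------------------------------

def choices_to_frame(record: GameRecord, subject_id: str, experiment: int,
                     condition: str, game: int) -> pd.DataFrame:
    rows = []
    for i, (state, action) in enumerate(record.choices):
        rows.append({"subject_id": subject_id, "experiment": experiment,
                     "condition": condition, "game": game, "move": i,
                     "prey_col": state.prey.col, "prey_row": state.prey.row,
                     "pred_col": state.predator.col,
                     "pred_row": state.predator.row,
                     "moves_left_in_turn": state.moves_left_in_turn,
                     "turns_left": state.turns_left, "action": action})
    return pd.DataFrame(rows)


def choices_from_frame(df: pd.DataFrame, env: Environment) -> list[tuple[JointState, str]]:
    """Rebuild (JointState, action) pairs for one game by replaying the CSV."""
    df = df.sort_values("move")
    coins = set(env.coins)
    out = []
    prey = env.prey_start
    for _, r in df.iterrows():
        state = JointState(prey=HexCell(int(r["prey_col"]), int(r["prey_row"])),
                           predator=HexCell(int(r["pred_col"]), int(r["pred_row"])),
                           coins_remaining=frozenset(coins),
                           whose_move="prey",
                           moves_left_in_turn=int(r["moves_left_in_turn"]),
                           turns_left=int(r["turns_left"]))
        out.append((state, r["action"]))
        prey = offset_neighbor(state.prey, r["action"])
        coins.discard(prey)
    return out


EXP3_CONDITIONS = tuple(f"{h}_{u}" for h in ("short", "long")
                        for u in ("predictable", "irreducible", "reducible"))


def exp3_env_spec(condition: str, seed: int = 0,
                  archetype: str = "approach") -> EnvironmentSpec:
    """Environment spec for an experiment-3 cell: short horizon is 1 prey /
    2 predator moves over 12 turns; long is 4 / 8 over 3 turns."""
    horizon = condition.split("_")[0]
    if horizon == "short":
        return EnvironmentSpec(archetype=archetype, moves_per_turn_prey=1,
                               moves_per_turn_predator=2, n_turns=12,
                               seed=seed, predator_col_frac=0.38,
                               approach_layout="transit")
    return EnvironmentSpec(archetype=archetype, moves_per_turn_prey=4,
                           moves_per_turn_predator=8, n_turns=3,
                           seed=seed, predator_col_frac=0.38,
                           approach_layout="transit")


def exp3_predator_rule(condition: str) -> ActionRule:
    """Predictable/reducible predators act greedily; the irreducible-
    uncertainty predator uses softmax with temperature 1."""
    return (ActionRule("softmax", 1.0) if condition.endswith("irreducible")
            else ActionRule("max"))


def simulate_planner_subject(envs: list[Environment],
                             subject: SimulatedSubjectSpec,
                             predator_rule: ActionRule | None = None,
                             subject_id: str = "s0", experiment: int = 2,
                             condition: str = "",
                             problems: list[PlanningProblem] | None = None,
                             weights=(1.0, 0.0, 0.0)):
    """Simulate one planner subject over ``envs`` (one game per env).

    Returns (game records, choices frame)."""
    params = PlannerParams(variant=subject.variant, tau_opp=subject.tau_opp,
                           theta=subject.theta,
                           n_simulations=subject.n_simulations)
    rng = random.Random(subject.seed)
    frames, records = [], []
    for g, env in enumerate(envs):
        problem = problems[g] if problems is not None else None
        rec = simulate_planner_game(env, weights, params,
                                    predator_rule=predator_rule,
                                    seed=rng.getrandbits(31), problem=problem)
        records.append(rec)
        frames.append(choices_to_frame(rec, subject_id, experiment,
                                       condition, g))
    return records, pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def simulate_experiment(exp: int, n_subjects: int, seed: int = 0,
                        n_games: int | None = None,
                        subject_spec: SimulatedSubjectSpec | None = None,
                        conditions=None, n_simulations: int = 300):
    """Simulate a full synthetic study and return a dict of data frames.

    Experiment 1 returns trajectories/predictions/ratings plus in-memory
    datasets; experiments 2 and 3 return planner choice frames plus game
    records.  Identical seeds reproduce identical bundles.
    """
    master = np.random.default_rng(seed)
    if exp == 1:
        conds = conditions or ("A", "B", "C")
        n_games = n_games or 6
        envs = [generate_environment(EnvironmentSpec(
            archetype="decoupled", seed=seed * 1000 + g)) for g in range(n_games)]
        all_pred, all_rate, all_traj = [], [], []
        datasets = {}
        for i in range(n_subjects):
            cond = conds[i % len(conds)]
            sub = subject_spec or SimulatedSubjectSpec(
                W=float(np.clip(master.normal(0.87, 0.1), 0.05, 1.0)),
                alpha=float(master.uniform(0.2, 0.9)),
                lam=float(master.uniform(0.0, 1.0)),
                rating_noise_sd=1.0)
            sub = SimulatedSubjectSpec(**{**sub.__dict__,
                                          "seed": int(master.integers(2 ** 31))})
            sid = f"s{i:03d}"
            trajs, preds, rates, dss = simulate_prediction_subject(
                envs, cond, sub, subject_id=sid)
            all_pred.append(preds)
            all_rate.append(rates)
            datasets[sid] = dss
            for g, t in enumerate(trajs):
                all_traj.append(trajectory_to_frame(
                    t, subject_id=sid, experiment=1, condition=cond, game=g,
                    moves_per_turn={"prey": 1, "predator": 2}))
        return {"environments": envs,
                "trajectories": pd.concat(all_traj, ignore_index=True),
                "predictions": pd.concat(all_pred, ignore_index=True),
                "ratings": pd.concat(all_rate, ignore_index=True),
                "datasets": datasets}
    if exp == 2:
        n_each = (n_games or 6) // 2
        envs, conds = [], []
        for k in range(n_each):
            envs.append(generate_environment(EnvironmentSpec(
                archetype="approach", moves_per_turn_prey=4,
                moves_per_turn_predator=6, n_turns=2, seed=seed * 100 + k)))
            conds.append("approach")
        for k in range(n_each):
            envs.append(generate_environment(EnvironmentSpec(
                archetype="avoid", moves_per_turn_prey=4,
                moves_per_turn_predator=6, n_turns=2, seed=seed * 100 + 50 + k)))
            conds.append("avoid")
        problems = [PlanningProblem(e, (1.0, 0.0, 0.0)) for e in envs]
        frames, records = [], {}
        for i in range(n_subjects):
            sub = subject_spec or SimulatedSubjectSpec(
                role="planner", theta=float(master.uniform(0.25, 1.5)),
                tau_opp=0.0, n_simulations=n_simulations)
            sub = SimulatedSubjectSpec(**{**sub.__dict__,
                                          "seed": int(master.integers(2 ** 31))})
            sid = f"s{i:03d}"
            recs, rows = [], []
            for g, (env, cond) in enumerate(zip(envs, conds)):
                rec = simulate_planner_game(
                    env, (1.0, 0.0, 0.0),
                    PlannerParams(variant=sub.variant, tau_opp=sub.tau_opp,
                                  theta=sub.theta,
                                  n_simulations=sub.n_simulations),
                    seed=int(master.integers(2 ** 31)), problem=problems[g])
                recs.append(rec)
                rows.append(choices_to_frame(rec, sid, 2, cond, g))
            records[sid] = recs
            frames.append(pd.concat(rows, ignore_index=True))
        return {"environments": envs, "conditions": conds,
                "problems": problems,
                "choices": pd.concat(frames, ignore_index=True),
                "records": records}
    if exp == 3:
        conds = conditions or EXP3_CONDITIONS
        frames, records, env_by_cond = [], {}, {}
        for ci, cond in enumerate(conds):
            env = generate_environment(exp3_env_spec(cond, seed=seed * 10 + ci))
            env_by_cond[cond] = env
            problem = PlanningProblem(env, (1.0, 0.0, 0.0))
            rule = exp3_predator_rule(cond)
            for i in range(n_subjects):
                sub = subject_spec or SimulatedSubjectSpec(
                    role="planner", theta=float(master.uniform(0.0, 2.0)),
                    tau_opp=float(master.uniform(0.0, 2.0)),
                    n_simulations=n_simulations)
                sid = f"{cond}_s{i:03d}"
                rec = simulate_planner_game(
                    env, (1.0, 0.0, 0.0),
                    PlannerParams(variant="mcts-rw", tau_opp=sub.tau_opp,
                                  theta=sub.theta,
                                  n_simulations=sub.n_simulations),
                    seed=int(master.integers(2 ** 31)), problem=problem)
                records[sid] = rec
                frames.append(choices_to_frame(rec, sid, 3, cond, 0))
        return {"environments": env_by_cond,
                "choices": pd.concat(frames, ignore_index=True),
                "records": records}
    raise ValueError("exp must be 1, 2, or 3")
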