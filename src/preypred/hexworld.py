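"""Hexagonal-grid world, feature-based MDP construction, and the turn-based game engine.

The task world is a ``width x height`` grid of flat-top hexagons in "odd-q"
offset coordinates (odd columns shifted half a cell downward; origin ``(0, 0)``
is the top-left cell, rows increase downward).  Cells can be removed to form
walls.  Three binary features live on cells -- trees, red ground, and the prey's
current position -- and a predator values a cell through the dot product
``f(s) . r`` of its feature vector with a reward-weight vector.

The six movement directions are listed in ring order (60 degrees apart), which
downstream models rely on when smoothing over adjacent actions::

    n, ne, se, s, sw, nw
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

DIRECTIONS: tuple[str, ...] = ("n", "ne", "se", "s", "sw", "nw")
DIR_INDEX = {d: i for i, d in enumerate(DIRECTIONS)}
N_DIRECTIONS = 6

FEATURES: tuple[str, ...] = ("trees", "red_ground", "prey")
N_FEATURES = 3

# Offset deltas (dcol, drow) for flat-top odd-q hexes, y increasing downward.
_OFFSETS_EVEN = {"n": (0, -1), "ne": (1, -1), "se": (1, 0),
                 "s": (0, 1), "sw": (-1, 0), "nw": (-1, -1)}
_OFFSETS_ODD = {"n": (0, -1), "ne": (1, 0), "se": (1, 1),
                "s": (0, 1), "sw": (-1, 1), "nw": (-1, 0)}


class HexCell(NamedTuple):
    col: int
    row: int


class InvalidCellError(ValueError):
    """Raised when an operation receives a wall or out-of-bounds cell."""


class InvalidActionError(ValueError):
    """Raised when a move would leave the grid or enter a wall."""


@dataclass(frozen=True)
class Environment:
    """A single game environment: grid size, walls, features, coins, starts.

    ``rich_zone`` annotates the cluster of concentrated coins used to quantify
    approach/avoidance; it may be empty for environments where that analysis
    does not apply.
    """

    width: int = 21
    height: int = 10
    walls: frozenset[HexCell] = field(default_factory=frozenset)
    trees: frozenset[HexCell] = field(default_factory=frozenset)
    red_ground: frozenset[HexCell] = field(default_factory=frozenset)
    coins: frozenset[HexCell] = field(default_factory=frozenset)
    predator_start: HexCell = HexCell(0, 0)
    prey_start: HexCell = HexCell(1, 0)
    rich_zone: frozenset[HexCell] = field(default_factory=frozenset)
    moves_per_turn_prey: int = 1
    moves_per_turn_predator: int = 2
    n_turns: int = 10

    def __post_init__(self) -> None:
        for name in ("walls", "trees", "red_ground", "coins", "rich_zone"):
            value = getattr(self, name)
            object.__setattr__(self, name,
                               frozenset(HexCell(*c) for c in value))
        object.__setattr__(self, "predator_start", HexCell(*self.predator_start))
        object.__setattr__(self, "prey_start", HexCell(*self.prey_start))
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must be at least 1x1")
        if self.moves_per_turn_prey < 1 or self.moves_per_turn_predator < 1:
            raise ValueError("moves per turn must be >= 1")
        for name in ("trees", "red_ground", "coins", "rich_zone"):
            bad = getattr(self, name) & self.walls
            if bad:
                raise ValueError(f"{name} overlaps walls: {sorted(bad)}")
        for start in (self.predator_start, self.prey_start):
            if not self.in_bounds(start) or start in self.walls:
                raise InvalidCellError(f"start cell {start} is a wall or out of bounds")
        if self.predator_start == self.prey_start:
            raise ValueError("predator and prey cannot share a start cell")

    # -- geometry ---------------------------------------------------------
    def in_bounds(self, cell: HexCell) -> bool:
        return 0 <= cell.col < self.width and 0 <= cell.row < self.height

    def is_state(self, cell: HexCell) -> bool:
        return self.in_bounds(cell) and cell not in self.walls

    def cells(self) -> list[HexCell]:
        """All non-wall cells in column-major order (the canonical state order)."""
        return [HexCell(c, r) for c in range(self.width) for r in range(self.height)
                if HexCell(c, r) not in self.walls]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def pairs(cells: Iterable[HexCell]) -> list[list[int]]:
            return [[c.col, c.row] for c in sorted(cells)]

        return {
            "width": self.width, "height": self.height,
            "walls": pairs(self.walls), "trees": pairs(self.trees),
            "red_ground": pairs(self.red_ground), "coins": pairs(self.coins),
            "predator_start": list(self.predator_start),
            "prey_start": list(self.prey_start),
            "rich_zone": pairs(self.rich_zone),
            "moves_per_turn": {"prey": self.moves_per_turn_prey,
                               "predator": self.moves_per_turn_predator},
            "n_turns": self.n_turns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        mpt = d.get("moves_per_turn", {})
        return cls(
            width=d["width"], height=d["height"],
            walls=frozenset(HexCell(*c) for c in d.get("walls", [])),
            trees=frozenset(HexCell(*c) for c in d.get("trees", [])),
            red_ground=frozenset(HexCell(*c) for c in d.get("red_ground", [])),
            coins=frozenset(HexCell(*c) for c in d.get("coins", [])),
            predator_start=HexCell(*d["predator_start"]),
            prey_start=HexCell(*d["prey_start"]),
            rich_zone=frozenset(HexCell(*c) for c in d.get("rich_zone", [])),
            moves_per_turn_prey=mpt.get("prey", 1),
            moves_per_turn_predator=mpt.get("predator", 2),
            n_turns=d.get("n_turns", 10),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Environment":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def offset_neighbor(cell: HexCell, direction: str) -> HexCell:
    """The cell one step from ``cell`` in ``direction`` (may be off-grid)."""
    table = _OFFSETS_ODD if cell.col % 2 else _OFFSETS_EVEN
    dc, dr = table[direction]
    return HexCell(cell.col + dc, cell.row + dr)


def neighbors(env: Environment, cell: HexCell) -> list[tuple[str, HexCell]]:
    """Passable neighbors of ``cell`` as ``(direction, cell)`` pairs in canonical order."""
    if not env.is_state(cell):
        raise InvalidCellError(f"{cell} is a wall or out of bounds")
    out = []
    for d in DIRECTIONS:
        nxt = offset_neighbor(cell, d)
        if env.is_state(nxt):
            out.append((d, nxt))
    return out


def feature_vector(env: Environment, cell: HexCell, prey_at: HexCell) -> np.ndarray:
    """Binary feature vector (trees, red_ground, prey) of ``cell``."""
    if not env.is_state(cell):
        raise InvalidCellError(f"{cell} is a wall or out of bounds")
    return np.array([cell in env.trees, cell in env.red_ground, cell == prey_at],
                    dtype=float)


@dataclass
class FeatureMDP:
    """A deterministic feature-based MDP over the environment's passable cells.

    Arrays are indexed by canonical state order; ``transition[s, a]`` holds the
    successor state index or -1 for unavailable actions.  The reward of an
    available action is the entered state's feature vector dotted with the
    reward weights: ``R(s, a) = f(s') . r``.
    """

    env: Environment
    states: list[HexCell]
    index: dict[HexCell, int]
    transition: np.ndarray            # (S, 6) int, -1 where unavailable
    valid: np.ndarray                 # (S, 6) bool
    features: np.ndarray              # (S, 3) binary, prey feature baked in
    weights: np.ndarray               # (3,)
    reward: np.ndarray                # (S, 6), 0 where unavailable
    discount: float
    prey_at: HexCell

    @property
    def n_states(self) -> int:
        return len(self.states)

    def actions(self, state: HexCell) -> list[str]:
        s = self.index[state]
        return [DIRECTIONS[a] for a in range(N_DIRECTIONS) if self.valid[s, a]]


def build_mdp(env: Environment, weights: Sequence[float], prey_at: HexCell,
              discount: float = 0.9) -> FeatureMDP:
    """Construct the feature MDP with the prey pinned at ``prey_at``."""
    if not 0.0 <= discount < 1.0:
        raise ValueError("discount must lie in [0, 1)")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (N_FEATURES,) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be a finite length-3 vector")
    states = env.cells()
    if not states:
        raise ValueError("environment has no passable states")
    index = {c: i for i, c in enumerate(states)}
    S = len(states)
    transition = np.full((S, N_DIRECTIONS), -1, dtype=np.int64)
    for i, cell in enumerate(states):
        for d, nxt in neighbors(env, cell):
            transition[i, DIR_INDEX[d]] = index[nxt]
    valid = transition >= 0
    features = np.zeros((S, N_FEATURES))
    for i, cell in enumerate(states):
        features[i] = feature_vector(env, cell, prey_at)
    reward = np.zeros((S, N_DIRECTIONS))
    reward[valid] = features[transition[valid]] @ weights
    return FeatureMDP(env=env, states=states, index=index, transition=transition,
                      valid=valid, features=features, weights=weights,
                      reward=reward, discount=discount, prey_at=prey_at)


@dataclass(frozen=True)
class GameState:
    """Snapshot of a game in progress; points follow the task's scoring rule
    (100 per coin collected, -1000 on capture)."""

    prey: HexCell
    predator: HexCell
    coins_remaining: frozenset[HexCell]
    points: int = 0
    turn: int = 0
    captured: bool = False

    @classmethod
    def initial(cls, env: Environment) -> "GameState":
        return cls(prey=env.prey_start, predator=env.predator_start,
                   coins_remaining=env.coins)


def step_game(state: GameState, env: Environment, actor: str, action: str,
              symmetric_capture: bool = True) -> GameState:
    """Apply one move by ``actor`` ("prey" or "predator").

    The prey collects a coin (+100 points) on entering a coin cell.  Capture
    (-1000 points) fires on co-location; by default after either actor's move,
    or only after the predator's with ``symmetric_capture=False``.
    """
    if state.captured:
        raise ValueError("game already ended by capture")
    if actor not in ("prey", "predator"):
        raise ValueError(f"unknown actor {actor!r}")
    pos = state.prey if actor == "prey" else state.predator
    if action not in DIRECTIONS:
        raise InvalidActionError(f"unknown direction {action!r}")
    nxt = offset_neighbor(pos, action)
    if not env.is_state(nxt):
        raise InvalidActionError(f"{actor} cannot move {action} from {pos}")
    prey, predator = state.prey, state.predator
    coins, points = state.coins_remaining, state.points
    if actor == "prey":
        prey = nxt
        if nxt in coins:
            coins = coins - {nxt}
            points += 100
    else:
        predator = nxt
    captured = (predator == prey) if (actor == "predator" or symmetric_capture) else False
    if captured:
        points -= 1000
    return replace(state, prey=prey, predator=predator, coins_remaining=coins,
                   points=points, captured=captured)


@dataclass(frozen=True)
class TrajectoryStep:
    """One move: who moved, from where, in which direction, and where the prey
    was at that moment (the feature-map snapshot)."""

    actor: str
    state: HexCell
    action: str
    next_state: HexCell
    prey_at: HexCell


@dataclass
class Trajectory:
    """Time-ordered moves of one game, with per-step prey snapshots."""

    steps: list[TrajectoryStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def predator_steps(self) -> list[TrajectoryStep]:
        return [s for s in self.steps if s.actor == "predator"]

    def prey_positions(self) -> list[HexCell]:
        return [s.next_state for s in self.steps if s.actor == "prey"]


TRAJECTORY_COLUMNS = ["subject_id", "experiment", "condition", "game",
                      "turn", "step", "actor", "col", "row", "action"]


def trajectory_to_frame(traj: Trajectory, subject_id: str = "sim",
                        experiment: int = 1, condition: str = "",
                        game: int = 0, moves_per_turn: dict | None = None) -> pd.DataFrame:
    """Flatten a trajectory to the canonical CSV schema (one row per move;
    ``col``/``row`` give the cell the actor moved *from*)."""
    rows = []
    counts = {"prey": 0, "predator": 0}
    mpt = moves_per_turn or {"prey": 1, "predator": 2}
    for i, st in enumerate(traj.steps):
        turn = counts[st.actor] // mpt[st.actor]
        rows.append({"subject_id": subject_id, "experiment": experiment,
                     "condition": condition, "game": game, "turn": turn,
                     "step": i, "actor": st.actor, "col": st.state.col,
                     "row": st.state.row, "action": st.action})
        counts[st.actor] += 1
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def trajectory_from_frame(df: pd.DataFrame, env: Environment) -> Trajectory:
    """Rebuild a single game's trajectory from canonical CSV rows, replaying
    moves to recover per-step prey snapshots."""
    df = df.sort_values("step")
    prey_at = env.prey_start
    steps = []
    for _, r in df.iterrows():
        cell = HexCell(int(r["col"]), int(r["row"]))
        nxt = offset_neighbor(cell, r["action"])
        if not env.is_state(nxt):
            raise InvalidActionError(f"row {r['step']} moves into a wall")
        if r["actor"] == "prey":
            prey_at = nxt
        steps.append(TrajectoryStep(actor=r["actor"], state=cell,
                                    action=r["action"], next_state=nxt,
                                    prey_at=prey_at))
    return Trajectory(steps=steps)
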