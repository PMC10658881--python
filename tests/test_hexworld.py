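import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preypred.hexworld import (DIRECTIONS, Environment, GameState, HexCell,
                               InvalidActionError, InvalidCellError,
                               _OFFSETS_EVEN, _OFFSETS_ODD, build_mdp,
                               feature_vector, neighbors, offset_neighbor,
                               step_game, trajectory_from_frame,
                               trajectory_to_frame)
from preypred.predator_agent import ActionRule, simulate_predator
from preypred.synthetic_data import random_prey_path
import random


def brute_force_neighbor_count(width, height, cell):
    """Independent oracle: enumerate the six offset rules and drop
    out-of-bounds results."""
    table = _OFFSETS_ODD if cell.col % 2 else _OFFSETS_EVEN
    n = 0
    for dc, dr in table.values():
        c, r = cell.col + dc, cell.row + dr
        n += (0 <= c < width) and (0 <= r < height)
    return n


class TestNeighbors:
    def test_interior_cell_has_six_neighbors(self, default_env):
        assert len(neighbors(default_env, HexCell(10, 5))) == 6

    @pytest.mark.parametrize("cell", [HexCell(0, 0), HexCell(20, 0),
                                      HexCell(0, 9), HexCell(20, 9),
                                      HexCell(0, 5), HexCell(7, 0)])
    def test_edge_counts_match_offset_enumeration(self, cell):
        env = Environment()
        expected = brute_force_neighbor_count(env.width, env.height, cell)
        assert len(neighbors(env, cell)) == expected

    def test_fully_enclosed_cell_has_no_neighbors(self):
        center = HexCell(3, 3)
        ring = {offset_neighbor(center, d) for d in DIRECTIONS}
        env = Environment(width=7, height=7, walls=frozenset(ring),
                          predator_start=HexCell(0, 0), prey_start=center)
        assert neighbors(env, center) == []

    def test_wall_or_out_of_bounds_input_rejected(self):
        env = Environment(walls=frozenset({HexCell(5, 5)}),
                          predator_start=HexCell(0, 0),
                          prey_start=HexCell(1, 0))
        with pytest.raises(InvalidCellError):
            neighbors(env, HexCell(5, 5))
        with pytest.raises(InvalidCellError):
            neighbors(env, HexCell(-1, 0))

    @given(col=st.integers(0, 20), row=st.integers(0, 9))
    @settings(max_examples=60, deadline=None)
    def test_neighbor_relation_is_symmetric(self, col, row):
        env = Environment()
        cell = HexCell(col, row)
        for _, nxt in neighbors(env, cell):
            assert cell in [c for _, c in neighbors(env, nxt)]


class TestEnvironment:
    def test_default_grid_has_210_states(self):
        assert len(Environment().cells()) == 210

    def test_json_round_trip(self, tmp_path, default_env):
        path = tmp_path / "env.json"
        default_env.to_json(path)
        assert Environment.from_json(path) == default_env

    def test_feature_sets_may_not_overlap_walls(self):
        with pytest.raises(ValueError):
            Environment(walls=frozenset({HexCell(3, 3)}),
                        trees=frozenset({HexCell(3, 3)}),
                        predator_start=HexCell(0, 0),
                        prey_start=HexCell(1, 0))


class TestFeatureVector:
    def test_tree_cell_with_prey(self, default_env):
        fv = feature_vector(default_env, HexCell(15, 3), prey_at=HexCell(15, 3))
        assert fv.tolist() == [1, 0, 1]

    def test_empty_cell(self, default_env):
        assert feature_vector(default_env, HexCell(2, 2),
                              HexCell(10, 5)).tolist() == [0, 0, 0]

    def test_red_ground_cell(self, default_env):
        assert feature_vector(default_env, HexCell(4, 6),
                              HexCell(10, 5)).tolist() == [0, 1, 0]


class TestBuildMdp:
    def test_zero_weights_give_zero_reward(self, default_env):
        mdp = build_mdp(default_env, (0, 0, 0), default_env.prey_start, 0.9)
        assert np.all(mdp.reward == 0)

    def test_entering_a_tree_cell_yields_its_weight(self, default_env):
        mdp = build_mdp(default_env, (1, 0, 0), default_env.prey_start, 0.9)
        s = mdp.index[HexCell(14, 3)]
        entering = [a for a in range(6)
                    if mdp.valid[s, a] and
                    mdp.states[mdp.transition[s, a]] in default_env.trees]
        assert entering and all(mdp.reward[s, a] == 1.0 for a in entering)

    def test_prey_reward_moves_with_the_prey(self, default_env):
        prey0, prey1 = HexCell(10, 5), HexCell(12, 5)
        s_cell = HexCell(10, 4)
        mdp0 = build_mdp(default_env, (0, 0, 1), prey0, 0.9)
        s = mdp0.index[s_cell]
        a = next(a for a in range(6) if mdp0.valid[s, a]
                 and mdp0.states[mdp0.transition[s, a]] == prey0)
        assert mdp0.reward[s, a] == 1.0
        mdp1 = build_mdp(default_env, (0, 0, 1), prey1, 0.9)
        assert mdp1.reward[s, a] == 0.0

    def test_action_counts_match_passable_neighbors(self, default_env):
        mdp = build_mdp(default_env, (0, 0, 0), default_env.prey_start, 0.9)
        for cell in [HexCell(0, 0), HexCell(10, 5), HexCell(20, 9)]:
            assert mdp.valid[mdp.index[cell]].sum() == \
                len(neighbors(default_env, cell))


class TestStepGame:
    def test_prey_collects_coin(self, default_env):
        gs = GameState(prey=HexCell(8, 3), predator=default_env.predator_start,
                       coins_remaining=default_env.coins)
        moved = step_game(gs, default_env, "prey", "n")  # (8,3) -> coin (8,2)
        assert moved.points == 100
        assert HexCell(8, 2) not in moved.coins_remaining

    def test_predator_capture_costs_1000(self, default_env):
        gs = GameState(prey=HexCell(10, 5), predator=HexCell(10, 4),
                       coins_remaining=default_env.coins)
        out = step_game(gs, default_env, "predator", "s")
        assert out.captured and out.points == -1000

    def test_empty_move_changes_only_position(self, default_env):
        gs = GameState.initial(default_env)
        out = step_game(gs, default_env, "prey", "n")
        assert out.points == 0 and out.prey == HexCell(10, 4)
        assert out.coins_remaining == gs.coins_remaining

    def test_invalid_move_raises(self, default_env):
        gs = GameState(prey=HexCell(0, 0), predator=HexCell(5, 5),
                       coins_remaining=frozenset())
        with pytest.raises(InvalidActionError):
            step_game(gs, default_env, "prey", "n")

    def test_points_accounting_over_random_game(self, default_env):
        rng = random.Random(3)
        gs = GameState.initial(default_env)
        coins0 = len(gs.coins_remaining)
        for _ in range(60):
            if gs.captured:
                break
            actor = rng.choice(["prey", "predator"])
            pos = gs.prey if actor == "prey" else gs.predator
            moves = [d for d, _ in neighbors(default_env, pos)]
            gs = step_game(gs, default_env, actor, rng.choice(moves))
        collected = coins0 - len(gs.coins_remaining)
        assert gs.points == 100 * collected - 1000 * gs.captured


class TestTrajectoryIO:
    def test_csv_round_trip_preserves_moves(self, default_env):
        prey_path = random_prey_path(default_env, 5, random.Random(0))
        traj = simulate_predator(default_env, (1, 0, 0), prey_path,
                                 ActionRule("max"), seed=1)
        df = trajectory_to_frame(traj, subject_id="s1", game=2)
        back = trajectory_from_frame(df, default_env)
        assert [(s.state, s.action) for s in back.steps] == \
            [(s.state, s.action) for s in traj.steps]
        assert list(df.columns) == ["subject_id", "experiment", "condition",
                                    "game", "turn", "step", "actor", "col",
                                    "row", "action"]
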