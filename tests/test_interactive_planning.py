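import math
import random

import numpy as np
import pytest

from preypred.hexworld import Environment, HexCell
from preypred.interactive_planning import (IBSEstimate, JointState,
                                           PlannerParams, PlanningProblem,
                                           estimate_planner_params,
                                           ibs_loglik, joint_state_count,
                                           mcts_choose, planner_ibs_loglik,
                                           simulate_planner_game)
from preypred.predator_agent import ActionRule
from preypred.synthetic_data import EnvironmentSpec, generate_environment


def initial_state(env):
    return JointState(prey=env.prey_start, predator=env.predator_start,
                      coins_remaining=env.coins, whose_move="prey",
                      moves_left_in_turn=env.moves_per_turn_prey,
                      turns_left=env.n_turns)


class TestJointState:
    def test_wall_free_grid_has_44100_position_states(self):
        assert joint_state_count(Environment()) == 210 ** 2

    def test_walls_reduce_the_count_quadratically(self):
        env = Environment(walls=frozenset({HexCell(3, 3), HexCell(4, 4)}),
                          predator_start=HexCell(0, 0), prey_start=HexCell(1, 0))
        assert joint_state_count(env) == 208 ** 2


class TestMctsChoose:
    def test_coin_side_of_a_corridor_is_chosen(self, corridor_env):
        # coin two steps west; the predator is unreachable within the game,
        # so every variant should walk west (exhaustive reasoning: the only
        # rewarded leaf of the game tree lies west)
        problem = PlanningProblem(corridor_env, (1.0, 0.0, 0.0))
        state = initial_state(corridor_env)
        west = {"nw", "sw"}
        for variant in ("mcts", "mcts-rand", "mcts-rw"):
            hits = 0
            for s in range(20):
                choice = mcts_choose(state, problem,
                                     PlannerParams(variant=variant,
                                                   n_simulations=500),
                                     random.Random(s))
                hits += choice in west
            assert hits >= 19

    def test_root_visits_sum_to_simulation_count(self, corridor_env):
        problem = PlanningProblem(corridor_env, (1.0, 0.0, 0.0))
        _, stats = mcts_choose(initial_state(corridor_env), problem,
                               PlannerParams(variant="mcts-rw",
                                             n_simulations=333),
                               random.Random(0), return_stats=True)
        assert sum(stats.values()) == 333

    def test_cold_softmax_opponent_matches_max_rule(self, corridor_env):
        problem = PlanningProblem(corridor_env, (1.0, 0.0, 0.0))
        state = initial_state(corridor_env)
        for s in range(5):
            a_max = mcts_choose(state, problem,
                                PlannerParams(variant="mcts-rw", tau_opp=0.0,
                                              n_simulations=200),
                                random.Random(s))
            a_cold = mcts_choose(state, problem,
                                 PlannerParams(variant="mcts-rw", tau_opp=1e-6,
                                               n_simulations=200),
                                 random.Random(s))
            assert a_max == a_cold

    def test_zero_threat_sensitivity_is_coin_greedy(self):
        env = generate_environment(EnvironmentSpec(
            archetype="avoid", moves_per_turn_prey=4, moves_per_turn_predator=6,
            n_turns=2, seed=0))
        problem = PlanningProblem(env, (1.0, 0.0, 0.0))
        entered = []
        for s in range(8):
            rec = simulate_planner_game(
                env, (1.0, 0.0, 0.0),
                PlannerParams(variant="mcts-rw", theta=0.0,
                              n_simulations=300),
                seed=s, problem=problem)
            entered.append(any(p in env.rich_zone for p in rec.prey_positions))
        assert np.mean(entered) > 0.5

    def test_rejects_non_prey_turns_and_empty_budgets(self, corridor_env):
        problem = PlanningProblem(corridor_env, (1.0, 0.0, 0.0))
        state = initial_state(corridor_env)
        with pytest.raises(ValueError):
            PlannerParams(variant="mcts-rw", n_simulations=0)
        bad = JointState(prey=state.prey, predator=state.predator,
                         coins_remaining=state.coins_remaining,
                         whose_move="predator")
        with pytest.raises(ValueError):
            mcts_choose(bad, problem, PlannerParams(variant="mcts"))


class TestIBS:
    def test_perfect_model_has_zero_loglik(self):
        est = ibs_loglik(lambda ctx, rng: "a", [(0, "a"), (1, "a")],
                         repeats=3, seed=0)
        assert est.loglik == 0.0
        assert est.per_trial_K == [1, 1]

    def test_match_on_fourth_draw_contributes_partial_harmonic_sum(self):
        calls = {"n": 0}

        def model(ctx, rng):
            calls["n"] += 1
            return "hit" if calls["n"] % 4 == 0 else "miss"

        est = ibs_loglik(model, [(0, "hit")], repeats=1, seed=0)
        assert est.loglik == pytest.approx(-(1 + 1 / 2 + 1 / 3))

    def test_bernoulli_estimates_are_unbiased(self):
        p = 0.3
        n = 80
        data = [(t, "y") for t in range(n)]
        vals = [ibs_loglik(lambda c, rng: "y" if rng.random() < p else "n",
                           data, repeats=1, seed=s).loglik
                for s in range(12)]
        exact = n * math.log(p)
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - exact) < 3 * se + 1e-9

    def test_cap_floors_the_contribution_and_flags(self):
        est = ibs_loglik(lambda ctx, rng: "never", [(0, "hit")], K_max=10,
                         repeats=1, seed=0)
        assert est.capped
        assert est.loglik == pytest.approx(-sum(1 / j for j in range(1, 10)))


class TestParameterEstimation:
    @pytest.fixture(scope="class")
    def avoid_setup(self):
        env = generate_environment(EnvironmentSpec(
            archetype="avoid", moves_per_turn_prey=4,
            moves_per_turn_predator=6, n_turns=2, seed=3))
        return env, PlanningProblem(env, (1.0, 0.0, 0.0))

    def test_coin_greedy_planner_lands_in_the_lowest_theta_cell(self, avoid_setup):
        env, problem = avoid_setup
        rec = simulate_planner_game(
            env, (1.0, 0.0, 0.0),
            PlannerParams(variant="mcts-rw", theta=0.0, n_simulations=200),
            seed=1, problem=problem)
        est = estimate_planner_params(
            rec.choices, problem, method="grid", tau_grid=(0.0,),
            theta_grid=(0.0, 1.0, 2.0), n_simulations=150, seed=0)
        assert est.theta == 0.0

    def test_threat_sensitive_cohorts_order_correctly(self, avoid_setup):
        env, problem = avoid_setup
        recovered = {0.0: [], 2.0: []}
        for theta in recovered:
            for s in range(3):
                rec = simulate_planner_game(
                    env, (1.0, 0.0, 0.0),
                    PlannerParams(variant="mcts-rw", theta=theta,
                                  n_simulations=200),
                    seed=10 + s, problem=problem)
                est = estimate_planner_params(
                    rec.choices, problem, method="grid", tau_grid=(0.0,),
                    theta_grid=(0.0, 1.0, 2.0), n_simulations=150,
                    seed=s)
                recovered[theta].append(est.theta)
        assert np.mean(recovered[0.0]) < np.mean(recovered[2.0])

    def test_rejection_sampling_returns_spread_and_mean(self, avoid_setup):
        env, problem = avoid_setup
        rec = simulate_planner_game(
            env, (1.0, 0.0, 0.0),
            PlannerParams(variant="mcts-rw", theta=1.0, n_simulations=150),
            seed=2, problem=problem)
        est = estimate_planner_params(rec.choices, problem,
                                      method="rejection", budget=30,
                                      n_simulations=100, seed=0)
        assert est.method == "rejection" and est.n_accepted == 3
        assert 0 <= est.theta <= 2.0
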