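import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preypred.action_prediction import (LearnerParams, PolicyEstimate,
                                        PredictionDataset, action_kernel,
                                        combine_predictions,
                                        fit_prediction_model,
                                        model_negloglik,
                                        predict_goal_inference, update_policy)
from preypred.hexworld import DIR_INDEX, Environment, HexCell
from preypred.recovery_harness import (_prediction_base_datasets,
                                       _simulate_prediction_dataset)


class TestUpdatePolicy:
    def test_first_observation_moves_half_way(self):
        est = update_policy(PolicyEstimate(), "se",
                            LearnerParams(alpha=0.5, lam=0.0))
        expect = np.zeros(6)
        expect[DIR_INDEX["se"]] = 0.5
        assert est.pi == pytest.approx(expect)
        assert est.n == 1

    def test_decay_halves_the_second_learning_rate(self):
        params = LearnerParams(alpha=0.5, lam=1.0)
        est = update_policy(PolicyEstimate(), "n", params)
        est = update_policy(est, "n", params)
        # second update uses alpha * 2^-1 = 0.25: 0.5 + 0.25*(1-0.5)
        assert est.pi[DIR_INDEX["n"]] == pytest.approx(0.625)

    def test_tiny_length_scale_reduces_to_plain_update(self):
        p_plain = update_policy(PolicyEstimate(), "ne",
                                LearnerParams(alpha=0.7))
        p_gen = update_policy(PolicyEstimate(), "ne",
                              LearnerParams(alpha=0.7, length_scale=1e-4),
                              generalize=True)
        assert np.allclose(p_plain.pi, p_gen.pi, atol=1e-9)

    def test_kernel_spreads_equally_to_ring_neighbors(self):
        k = action_kernel(0.2)
        row = k[DIR_INDEX["se"]]
        # ring order: the two actions 60 degrees away get equal mass
        assert row[DIR_INDEX["ne"]] == pytest.approx(row[DIR_INDEX["s"]])
        assert row[DIR_INDEX["se"]] > row[DIR_INDEX["ne"]]

    def test_kernel_rows_conserve_unit_mass(self):
        for ls in (0.05, 0.15, 0.5):
            assert action_kernel(ls).sum(axis=1) == pytest.approx(np.ones(6))

    @given(alpha=st.floats(0.05, 1.0), lam=st.floats(0.0, 2.0),
           seq=st.lists(st.sampled_from(["n", "ne", "se", "s", "sw", "nw"]),
                        min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_estimates_stay_in_unit_interval(self, alpha, lam, seq):
        est = PolicyEstimate()
        params = LearnerParams(alpha=alpha, lam=lam)
        for d in seq:
            est = update_policy(est, d, params)
            assert np.all(est.pi >= 0) and np.all(est.pi <= 1)


class TestGoalInference:
    def test_zero_weights_give_uniform_prediction(self, default_env):
        probs = predict_goal_inference(default_env, (0, 0, 0), HexCell(10, 5),
                                       default_env.prey_start)
        avail = probs[probs > 0]
        assert avail == pytest.approx(np.full(6, 1 / 6))

    def test_symmetric_rewards_get_symmetric_probabilities(self):
        # trees equidistant east and west of the center cell of a corridor
        env = Environment(width=5, height=1,
                          trees=frozenset({HexCell(0, 0), HexCell(4, 0)}),
                          predator_start=HexCell(2, 0), prey_start=HexCell(1, 0))
        probs = predict_goal_inference(env, (1, 0, 0), HexCell(2, 0),
                                       HexCell(1, 0))
        east, west = probs[DIR_INDEX["se"]], probs[DIR_INDEX["sw"]]
        assert east == pytest.approx(west, abs=1e-9)

    def test_modal_prediction_points_at_the_goal_not_the_heading(self):
        # the predator arrives travelling east; the trees lie north
        env = Environment(width=9, height=6,
                          trees=frozenset({HexCell(4, 0), HexCell(5, 0)}),
                          predator_start=HexCell(0, 4), prey_start=HexCell(8, 5))
        probs = predict_goal_inference(env, (1, 0, 0), HexCell(4, 4),
                                       env.prey_start)
        assert probs.argmax() == DIR_INDEX["n"]


class TestCombinePredictions:
    def test_w_one_preserves_goal_ranking(self):
        goal = np.array([0.4, 0.3, 0.2, 0.05, 0.03, 0.02])
        policy = np.array([0.0, 0.0, 0.9, 0.0, 0.1, 0.0])
        out = combine_predictions(goal, policy, W=1.0)
        assert np.argsort(out).tolist() == np.argsort(goal).tolist()

    def test_w_zero_preserves_policy_ranking(self):
        goal = np.array([0.4, 0.3, 0.2, 0.05, 0.03, 0.02])
        policy = np.array([0.05, 0.1, 0.9, 0.2, 0.3, 0.4])
        out = combine_predictions(goal, policy, W=0.0)
        assert np.argsort(out).tolist() == np.argsort(policy).tolist()

    def test_even_mixture_of_opposed_one_hots_is_symmetric(self):
        avail = np.zeros(6, dtype=bool)
        avail[:2] = True
        goal = np.array([1.0, 0, 0, 0, 0, 0])
        policy = np.array([0, 1.0, 0, 0, 0, 0])
        out = combine_predictions(goal, policy, W=0.5, avail=avail)
        assert out[0] == pytest.approx(out[1])
        assert out.sum() == pytest.approx(1.0)

    def test_constant_component_contributes_nothing(self):
        goal = np.full(6, 0.25)
        policy = np.array([0.0, 1.0, 0, 0, 0, 0])
        out = combine_predictions(goal, policy, W=0.5)
        assert out.argmax() == 1


@pytest.fixture(scope="module")
def base_dataset():
    return _prediction_base_datasets(1, seed=5, n_games=10, n_turns=10)[0]


class TestFitting:
    def test_single_trial_repeat_bic_is_twice_the_nll(self, base_dataset):
        one = PredictionDataset(avail=base_dataset.avail[:1],
                                goal_probs=base_dataset.goal_probs[:1],
                                observed=base_dataset.observed[:1],
                                predicted=base_dataset.predicted[:1])
        fit = fit_prediction_model(one, "repeat")
        assert fit.bic == pytest.approx(2 * fit.neg_loglik)  # k = 0

    def test_combined_model_dominates_its_components(self, base_dataset):
        data = _simulate_prediction_dataset(
            base_dataset, "combined", {"W": 0.6, "alpha": 0.5, "lam": 0.2},
            seed=3, length_scale=0.15)
        nll = {m: fit_prediction_model(data, m, seed=0,
                                       length_scale=0.15).neg_loglik
               for m in ("goal", "policy", "combined")}
        assert nll["combined"] <= nll["goal"] + 1e-6
        assert nll["combined"] <= nll["policy"] + 1e-6

    @pytest.mark.parametrize("true_W,bound,side", [(0.95, 0.9, "hi"),
                                                   (0.05, 0.1, "lo")])
    def test_extreme_mixture_weights_recover(self, base_dataset, true_W,
                                             bound, side):
        data = _simulate_prediction_dataset(
            base_dataset, "combined", {"W": true_W, "alpha": 0.6, "lam": 0.1},
            seed=11, length_scale=0.15)
        fit = fit_prediction_model(data, "combined", seed=1, length_scale=0.15)
        if side == "hi":
            assert fit.params["W"] >= bound
        else:
            assert fit.params["W"] <= bound

    def test_accuracy_counts_modal_agreement(self, base_dataset):
        data = _simulate_prediction_dataset(base_dataset, "goal", {}, seed=2,
                                            length_scale=0.15)
        fit = fit_prediction_model(data, "goal")
        nll, acc = model_negloglik(data, "goal", return_accuracy=True)
        assert fit.accuracy == pytest.approx(acc)
        assert 0 <= acc <= 1
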