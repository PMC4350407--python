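"""Choice rule, value updates, indecision points, trajectories, simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import rewardbias as rb
from rewardbias.models import (CONTEXT_DEPENDENT, CONTEXT_FREE, ModelParams,
                               UndefinedIndecisionError, ValueState,
                               choice_probability, indecision_point,
                               run_trajectory, simulate_agent,
                               update_context_dependent, update_context_free)

finite_params = st.builds(
    ModelParams,
    beta0=st.floats(-5, 5), beta1=st.floats(-10, 10),
    alpha=st.floats(0, 1),
)


class TestChoiceProbability:
    def test_symmetric_logit_gives_half(self):
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        p = choice_probability(state, 0, 0.0, ModelParams(2.0, 3.0, 0.1))
        assert p == pytest.approx(0.5)

    def test_strong_upward_coherence(self):
        # beta1 * S = 4.01 * 0.64 = 2.5664 -> logistic(2.5664)
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        p = choice_probability(state, 0, 0.64, ModelParams(0.81, 4.01, 0.02))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-2.5664)), abs=1e-12)
        assert p == pytest.approx(0.9286, abs=1e-3)

    def test_pure_value_advantage(self):
        state = ValueState.from_values(CONTEXT_FREE, [0.0, 1.0])  # down, up
        p = choice_probability(state, 0, 0.3, ModelParams(1.0, 0.0, 0.5))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    @given(params=finite_params, s=st.floats(-1, 1),
           dq=st.floats(-2, 2))
    @settings(max_examples=100, deadline=None)
    def test_up_and_down_probabilities_sum_to_one(self, params, s, dq):
        state = ValueState.from_values(CONTEXT_FREE, [0.0, dq])
        p_up = choice_probability(state, 0, s, params)
        mirrored = ValueState.from_values(CONTEXT_FREE, [dq, 0.0])
        p_down = 1.0 - p_up
        assert 0.0 < p_up < 1.0 or dq == 0
        assert p_up + p_down == pytest.approx(1.0)

    def test_monotone_in_coherence_and_value(self):
        params = ModelParams(0.8, 4.0, 0.1)
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        ps = [choice_probability(state, 0, s, params)
              for s in np.linspace(-1, 1, 21)]
        assert (np.diff(ps) > 0).all()
        ps_dq = [choice_probability(
            ValueState.from_values(CONTEXT_DEPENDENT, [0.0, dq]), 0, 0.0, params)
            for dq in np.linspace(-2, 2, 21)]
        assert (np.diff(ps_dq) > 0).all()


class TestValueUpdates:
    def test_delta_rule_arithmetic(self):
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        new, delta = update_context_dependent(state, 0, rb.UP, 2.0, 0.02)
        assert delta == pytest.approx(2.0)
        assert new.q[0, rb.UP] == pytest.approx(0.04)
        # only the (context, chosen) cell changed
        assert new.q[0, rb.DOWN] == 0.0 and (new.q[1] == 0.0).all()

    def test_zero_learning_rate_freezes_values(self):
        state = ValueState.from_values(CONTEXT_DEPENDENT, [[0.1, 0.2], [0.3, 0.4]])
        new, delta = update_context_dependent(state, 1, rb.DOWN, 2.0, 0.0)
        assert delta == pytest.approx(2.0 - 0.3)
        np.testing.assert_array_equal(new.q, state.q)

    def test_rpe_is_unscaled_by_learning_rate(self):
        state = ValueState.from_values(CONTEXT_FREE, [1.0, 0.0])
        new, delta = update_context_free(state, rb.DOWN, 0.0, 0.5)
        assert delta == pytest.approx(-1.0)
        assert new.q[0, rb.DOWN] == pytest.approx(0.5)

    def test_unchosen_direction_untouched(self):
        state = ValueState.from_values(CONTEXT_FREE, [0.7, 0.3])
        new, _ = update_context_free(state, rb.UP, 2.0, 0.4)
        assert new.q[0, rb.DOWN] == pytest.approx(0.7)

    def test_full_replacement_at_alpha_one(self):
        state = ValueState.from_values(CONTEXT_FREE, [0.7, 0.3])
        new, _ = update_context_free(state, rb.UP, 1.5, 1.0)
        assert new.q[0, rb.UP] == pytest.approx(1.5)

    @pytest.mark.parametrize("alpha,r,t", [(0.02, 2.0, 50), (0.3, 1.0, 10)])
    def test_constant_reward_geometric_series(self, alpha, r, t):
        # repeated reward r from Q0=0: Q_t = r * (1 - (1 - alpha)^t)
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        for _ in range(t):
            state, _ = update_context_dependent(state, 0, rb.UP, r, alpha)
        expected = r * (1.0 - (1.0 - alpha) ** t)
        assert state.q[0, rb.UP] == pytest.approx(expected, abs=1e-12)

    def test_learning_rate_bounds_enforced(self):
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        with pytest.raises(ValueError):
            update_context_dependent(state, 0, rb.UP, 1.0, 1.5)

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            update_context_free(ValueState.zeros(CONTEXT_DEPENDENT), rb.UP, 1., .1)


class TestIndecisionPoint:
    def test_unbiased_observer_at_zero(self):
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        assert indecision_point(state, 0, ModelParams(1.0, 3.0, 0.1)) == 0.0

    def test_closed_form_value(self):
        state = ValueState.from_values(CONTEXT_DEPENDENT, [0.0, 1.0])
        s_star = indecision_point(state, 0, ModelParams(0.81, 4.01, 0.02))
        assert s_star == pytest.approx(-0.81 / 4.01, abs=1e-12)
        assert s_star == pytest.approx(-0.2020, abs=1e-4)

    def test_matches_bisection_on_choice_rule(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            params = ModelParams(rng.uniform(0.1, 3), rng.uniform(0.5, 8),
                                 rng.uniform(0, 1))
            state = ValueState.from_values(
                CONTEXT_DEPENDENT, rng.uniform(-2, 2, size=(2, 2)))
            s_star = indecision_point(state, 1, params)
            root = brentq(lambda s: choice_probability(state, 1, s, params) - 0.5,
                          -50, 50, xtol=1e-12)
            assert abs(s_star - root) < 1e-8

    def test_zero_slope_is_undefined(self):
        state = ValueState.zeros(CONTEXT_DEPENDENT)
        with pytest.raises(UndefinedIndecisionError):
            indecision_point(state, 0, ModelParams(1.0, 0.0, 0.1))


def _toy_dataset():
    return pd.DataFrame({
        "trial_index": [1, 2, 3, 4, 5],
        "run": 1,
        "context": [0, 1, 0, 1, 0],
        "coherence": [0.12, -0.64, 0.0, 0.04, -0.12],
        "choice": [1, 0, 1, 1, 0],
        "reward": [2.0, 2.0, 0.0, 1.0, 1.0],
    })


class TestTrajectory:
    def test_matches_hand_rolled_loop(self, table1_params):
        data = _toy_dataset()
        traj = run_trajectory(data, table1_params, CONTEXT_DEPENDENT)
        # independent per-trial reference loop
        q = np.zeros((2, 2))
        for i, row in data.iterrows():
            c, m = int(row.context), int(row.choice)
            x = table1_params.beta0 * (q[c, 1] - q[c, 0]) \
                + table1_params.beta1 * row.coherence
            assert traj.loc[i, "p_up"] == pytest.approx(1 / (1 + math.exp(-x)))
            assert traj.loc[i, "q_up"] == pytest.approx(q[c, 1])
            assert traj.loc[i, "bias_amount"] == pytest.approx(abs(q[c, 1] - q[c, 0]))
            delta = row.reward - q[c, m]
            assert traj.loc[i, "rpe"] == pytest.approx(delta)
            q[c, m] += table1_params.alpha * delta

    def test_zero_learning_rate_keeps_bias_constant(self):
        data = _toy_dataset()
        params = ModelParams(1.0, 4.0, 0.0)
        q0 = np.array([[0.2, 0.9], [0.2, 0.9]])
        traj = run_trajectory(data, params, CONTEXT_DEPENDENT, q_init=q0)
        assert traj["bias_amount"].to_numpy() == pytest.approx(0.7)

    def test_models_coincide_on_single_context_data(self, table1_params):
        data = _toy_dataset()
        data["context"] = 0
        a = run_trajectory(data, table1_params, CONTEXT_DEPENDENT)
        b = run_trajectory(data, table1_params, CONTEXT_FREE)
        pd.testing.assert_series_equal(a["p_up"], b["p_up"])
        pd.testing.assert_series_equal(a["rpe"], b["rpe"])

    def test_missing_choice_with_reward_rejected(self, table1_params):
        data = _toy_dataset()
        data.loc[1, "choice"] = rb.NO_RESPONSE  # reward on this trial is 2.0
        with pytest.raises(ValueError, match="missing choice"):
            run_trajectory(data, table1_params, CONTEXT_DEPENDENT)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_q_values_stay_within_payoff_interval(self, seed):
        # delta-rule updates are convex combinations of Q and r
        rng = np.random.default_rng(seed)
        n = 40
        data = pd.DataFrame({
            "trial_index": np.arange(1, n + 1), "run": 1,
            "context": rng.integers(0, 2, n),
            "coherence": rng.choice([-0.64, 0.0, 0.64], n),
            "choice": rng.integers(0, 2, n),
            "reward": rng.choice([0.0, 1.0, 2.0], n),
        })
        params = ModelParams(rng.uniform(0, 2), rng.uniform(0, 6),
                             rng.uniform(0, 1))
        traj = run_trajectory(data, params, CONTEXT_DEPENDENT)
        assert traj[["q_up", "q_down"]].to_numpy().min() >= 0.0
        assert traj[["q_up", "q_down"]].to_numpy().max() <= 2.0

    def test_bias_grows_under_asymmetric_payoffs(self, agent_dataset,
                                                 table1_params):
        traj = run_trajectory(agent_dataset, table1_params, CONTEXT_DEPENDENT)
        assert (traj[traj["run"] == 5]["bias_amount"].mean()
                > traj[traj["run"] == 1]["bias_amount"].mean())


class TestSimulateAgent:
    def test_seeded_determinism(self, schedule, table1_params):
        a = simulate_agent(schedule, table1_params, seed=5)
        b = simulate_agent(schedule, table1_params, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_saturating_accuracy_at_high_coherence(self, schedule):
        params = ModelParams(0.0, 50.0, 0.0)
        ds = simulate_agent(schedule, params, CONTEXT_FREE, seed=1)
        strong = ds[ds["coherence"].abs() == 0.64]
        assert strong["correct"].mean() > 0.99

    def test_choice_rates_match_analytic_probabilities(self):
        # frozen values (alpha=0): empirical P(up) per coherence ~ logistic
        cfg = rb.TaskConfig(reps_per_cell=100, n_runs=5)
        sched = rb.build_trial_schedule(cfg, seed=3)
        params = ModelParams(1.0, 4.0, 0.0)
        q0 = np.array([[0.0, 0.5], [0.5, 0.0]])
        ds = simulate_agent(sched, params, CONTEXT_DEPENDENT, q_init=q0, seed=8)
        state = ValueState.from_values(CONTEXT_DEPENDENT, q0)
        for (c, s), grp in ds.groupby(["context", "coherence"]):
            p = choice_probability(state, c, s, params)
            n = len(grp)
            obs = (grp["choice"] == rb.UP).mean()
            assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-9
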