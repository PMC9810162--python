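import numpy as np
import pytest

from twostep.agent import (AgentParams, AgentState, choice_probability,
                           hybrid_values, internal_reward, mb_values,
                           simulate_subject, update_state)
from twostep.data import MISSING
from twostep.task import DEFAULT_TRANSITIONS, TaskConfig


class TestParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            AgentParams(omega=1.2)
        with pytest.raises(ValueError):
            AgentParams(beta=25.0)
        with pytest.raises(ValueError):
            AgentParams(alpha={"reward": -0.1})

    def test_resolve_scalar_and_split(self):
        p = AgentParams(omega={"protection": 0.8, "reward": 0.2}, alpha=0.5)
        assert p.resolve("omega", "protection", True) == 0.8
        assert p.resolve("alpha", "reward", False) == 0.5
        with pytest.raises(KeyError, match="no omega entry"):
            p.resolve("omega", "punishment", False)

    def test_resolve_stakes_split(self):
        p = AgentParams(omega={"low": 0.3, "high": 0.7})
        assert p.resolve("omega", "reward", True) == 0.7
        assert p.resolve("omega", "reward", False) == 0.3


class TestMbValues:
    def test_lookup_state0(self):
        q2 = np.array([3.0, 8.0])
        np.testing.assert_array_equal(
            mb_values(0, q2, DEFAULT_TRANSITIONS), [3.0, 8.0])

    def test_equivalence_state1(self):
        q2 = np.array([3.0, 8.0])
        np.testing.assert_array_equal(
            mb_values(1, q2, DEFAULT_TRANSITIONS), [8.0, 3.0])

    def test_generalization_across_states(self):
        # updating one creature's value changes planning from BOTH states
        agent = AgentState()
        before = [mb_values(s, agent.q_stage2.copy(), DEFAULT_TRANSITIONS)
                  for s in (0, 1)]
        update_state(0, 0, 0, 9.0, alpha=1.0, lam=0.0, agent=agent,
                     response_key=0)
        after = [mb_values(s, agent.q_stage2, DEFAULT_TRANSITIONS)
                 for s in (0, 1)]
        assert not np.allclose(before[0], after[0])
        assert not np.allclose(before[1], after[1])


class TestHybrid:
    def test_pure_mb(self):
        np.testing.assert_array_equal(
            hybrid_values(np.array([1.0, 2.0]), np.array([5.0, 6.0]), 1.0),
            [5.0, 6.0])

    def test_pure_mf(self):
        np.testing.assert_array_equal(
            hybrid_values(np.array([1.0, 2.0]), np.array([5.0, 6.0]), 0.0),
            [1.0, 2.0])

    def test_midpoint(self):
        np.testing.assert_allclose(
            hybrid_values(np.array([0.0, 4.0]), np.array([2.0, 0.0]), 0.5),
            [1.0, 2.0])

    def test_omega_out_of_range(self):
        with pytest.raises(ValueError):
            hybrid_values(np.zeros(2), np.zeros(2), 1.5)


class TestChoiceProbability:
    def test_indifferent_at_beta0(self):
        p = choice_probability(np.array([9.0, 0.0]), MISSING, 0, 0.0, 0.0)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_logistic_closed_form(self):
        p = choice_probability(np.array([2.0, 1.0]), MISSING, 0, 1.0, 0.0)
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-4)

    def test_stickiness_closed_form(self):
        # equal values; option 0 (shown left) repeats prev response key 0
        p = choice_probability(np.array([3.0, 3.0]), 0, 0, 1.0, 0.5)
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-0.5)), abs=1e-6)

    def test_first_trial_no_stick(self):
        p = choice_probability(np.array([3.0, 3.0]), MISSING, 0, 1.0, 0.9)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vals = rng.uniform(0, 9, 2)
            p = choice_probability(vals, int(rng.integers(2)),
                                   int(rng.integers(2)),
                                   rng.uniform(0, 20), rng.uniform(0, 1))
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0) and np.all(p <= 1)

    def test_open_interval_at_moderate_beta(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            vals = rng.uniform(0, 9, 2)
            p = choice_probability(vals, int(rng.integers(2)),
                                   int(rng.integers(2)),
                                   rng.uniform(0, 3), rng.uniform(0, 1))
            assert np.all(p > 0) and np.all(p < 1)


class TestUpdateState:
    def test_alpha_zero_freezes(self):
        agent = AgentState()
        update_state(0, 1, 1, 8.0, alpha=0.0, lam=1.0, agent=agent,
                     response_key=1)
        np.testing.assert_array_equal(agent.q_mf, np.full((2, 2), 4.5))
        np.testing.assert_array_equal(agent.q_stage2, [4.5, 4.5])
        assert agent.prev_key == 1

    def test_full_transfer(self):
        agent = AgentState(q_mf=np.zeros((2, 2)), q_stage2=np.zeros(2))
        update_state(0, 0, 0, 5.0, alpha=1.0, lam=1.0, agent=agent,
                     response_key=0)
        assert agent.q_stage2[0] == 5.0
        assert agent.q_mf[0, 0] == 5.0

    def test_no_trace_no_transfer(self):
        agent = AgentState(q_mf=np.zeros((2, 2)), q_stage2=np.zeros(2))
        update_state(0, 0, 0, 5.0, alpha=1.0, lam=0.0, agent=agent,
                     response_key=0)
        assert agent.q_stage2[0] == 5.0
        assert agent.q_mf[0, 0] == 0.0  # delta1 was 0 at choice time

    def test_values_stay_bounded_fuzz(self):
        rng = np.random.default_rng(4)
        agent = AgentState()
        for _ in range(2000):
            update_state(int(rng.integers(2)), int(rng.integers(2)),
                         int(rng.integers(2)), float(rng.integers(10)),
                         alpha=rng.uniform(), lam=rng.uniform(),
                         agent=agent, response_key=int(rng.integers(2)))
            assert np.all((agent.q_mf >= 0) & (agent.q_mf <= 9))
            assert np.all((agent.q_stage2 >= 0) & (agent.q_stage2 <= 9))


class TestInternalReward:
    @pytest.mark.parametrize("variant,outcome,expected", [
        ("reward", 7, 7.0),
        ("protection", 3, 3.0),
        ("direct_reward", 0, 0.0),
        ("punishment", 0, 9.0),
        ("punishment", 9, 0.0),
    ])
    def test_mapping(self, variant, outcome, expected):
        assert internal_reward(variant, outcome) == expected


class TestSimulate:
    def test_deterministic(self, basic_config):
        p = AgentParams(omega=0.5, beta=3.0)
        a, _ = simulate_subject(p, basic_config, seed=7)
        b, _ = simulate_subject(p, basic_config, seed=7)
        np.testing.assert_array_equal(a.choice, b.choice)
        np.testing.assert_array_equal(a.outcome_units, b.outcome_units)

    def test_greedy_planner_finds_best_creature_static_payoffs(self):
        # low-noise regime: frozen walks, near-deterministic policy
        cfg = TaskConfig(variant="reward", n_trials=100, n_practice=0,
                         walk_sigma=0.0)
        p = AgentParams(omega=1.0, alpha=0.9, lam=1.0, pi_stick=0.0,
                        beta=20.0)
        for seed in range(5):
            data, info = simulate_subject(p, cfg, seed=seed)
            best = int(np.argmax(info["walks"].values[0]))
            agree = np.mean(data.creature[20:] == best)
            assert agree > 0.8

    def test_greedy_planner_beats_chance_on_drifting_payoffs(self):
        cfg = TaskConfig(variant="reward", n_trials=200, n_practice=0)
        p = AgentParams(omega=1.0, alpha=0.9, lam=1.0, pi_stick=0.0,
                        beta=20.0)
        agree = []
        for seed in range(10):
            data, info = simulate_subject(p, cfg, seed=seed)
            best = np.argmax(info["walks"].values, axis=1)
            agree.append(np.mean(data.creature[30:] == best[30:]))
        assert np.mean(agree) > 0.55

    def test_beta0_visits_both(self):
        cfg = TaskConfig(variant="reward", n_trials=400, n_practice=0)
        p = AgentParams(omega=0.5, beta=0.0)
        data, _ = simulate_subject(p, cfg, seed=5)
        frac = np.mean(data.creature == 0)
        assert 0.4 < frac < 0.6

    def test_transition_consistency(self, sim_dataset):
        data, _, _ = sim_dataset
        ok = data.choice != MISSING
        np.testing.assert_array_equal(
            data.creature[ok],
            DEFAULT_TRANSITIONS[data.state[ok], data.choice[ok]])

    def test_missed_trials(self):
        cfg = TaskConfig(variant="reward", n_trials=100, n_practice=0,
                         miss_prob=0.3)
        data, _ = simulate_subject(AgentParams(), cfg, seed=1)
        missed = data.choice == MISSING
        assert 0.15 < missed.mean() < 0.45
        assert np.all(data.outcome_units[missed] == MISSING)
        assert np.all(data.final_result[missed] == MISSING)

    def test_final_result_magnitude_bounded(self, sim_dataset):
        data, _, _ = sim_dataset
        ok = data.final_result != MISSING
        assert np.all(data.final_result[ok] >= 0)
        assert np.all(data.final_result[ok] <= 45)
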