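import numpy as np
import pytest

from twostep.agent import AgentParams, simulate_subject
from twostep.data import MISSING, SubjectDataset
from twostep.likelihood import (PointwiseLogLik, negloglik_surface,
                                prepare_session, subject_loglik)
from twostep.task import DEFAULT_TRANSITIONS, TaskConfig


def make_dataset(trials, variant="reward", practice_flags=None):
    """Build a SubjectDataset from (state, left, choice, outcome) tuples."""
    n = len(trials)
    state, left, choice, outcome = map(np.array, zip(*trials))
    creature = np.where(choice >= 0,
                        DEFAULT_TRANSITIONS[state, np.maximum(choice, 0)],
                        MISSING)
    key = np.where(choice >= 0, (choice != left).astype(int), MISSING)
    practice = (np.zeros(n, dtype=bool) if practice_flags is None
                else np.asarray(practice_flags, dtype=bool))
    return SubjectDataset(
        subject_id="fix", variant=variant,
        trial_index=np.arange(n), practice=practice,
        stakes=np.ones(n, dtype=int), state=state, left_dwelling=left,
        choice=choice, response_key=key, creature=creature,
        outcome_units=outcome,
        final_result=np.where(choice >= 0, outcome, MISSING),
        certainty=np.full(n, MISSING), outcome_estimate=np.full(n, MISSING))


def naive_loglik(params, data):
    """Independent step-through re-implementation (plain python floats)."""
    import math
    q_mf = [[4.5, 4.5], [4.5, 4.5]]
    q2 = [4.5, 4.5]
    tmap = [[0, 1], [1, 0]]
    prev_key = None
    total, per = 0.0, []
    w = params.resolve("omega", data.variant, False)
    a = params.resolve("alpha", data.variant, False)
    for t in range(len(data)):
        ch = int(data.choice[t])
        if ch == MISSING:
            if not data.practice[t]:
                per.append(0.0)
            continue
        s = int(data.state[t])
        l = int(data.left_dwelling[t])
        v = [w * q2[tmap[s][d]] + (1 - w) * q_mf[s][d] for d in (0, 1)]
        if prev_key is not None:
            for d in (0, 1):
                if (0 if d == l else 1) == prev_key:
                    v[d] += params.pi_stick
        if not data.practice[t]:
            x = [params.beta * v[0], params.beta * v[1]]
            lp = x[ch] - math.log(math.exp(x[0]) + math.exp(x[1]))
            total += lp
            per.append(lp)
        cr = tmap[s][ch]
        r = float(data.outcome_units[t])
        if data.variant == "punishment":
            r = 9.0 - r
        q_mf[s][ch] += a * (q2[cr] - q_mf[s][ch])
        d2 = r - q2[cr]
        q2[cr] += a * d2
        q_mf[s][ch] += a * params.lam * d2
        prev_key = 0 if ch == l else 1
    return total, np.array(per)


FIXTURE_3TRIAL = [
    # (state, left_dwelling, choice, outcome)
    (0, 0, 0, 7),
    (1, 1, 1, 2),
    (0, 1, 0, 5),
]
FIXTURE_PARAMS = AgentParams(omega=0.6, alpha=0.5, lam=0.7,
                             pi_stick=0.3, beta=2.0)
# hand-stepped: ln(1/2) - ln(1+e^-2.1) - ln(1+e^0.65)
#   = -0.69314718 - 0.11551952 - 1.07005534
FIXTURE_LOGLIK = -1.8787220394424153


class TestSubjectLoglik:
    def test_single_trial_symmetric_start(self):
        data = make_dataset([(0, 0, 0, 5)])
        params = AgentParams(omega=0.5, alpha=0.5, pi_stick=0.0, beta=3.0)
        total, per = subject_loglik(params, data)
        assert total == pytest.approx(np.log(0.5), abs=1e-12)
        assert len(per) == 1

    def test_three_trial_hand_stepped_fixture(self):
        data = make_dataset(FIXTURE_3TRIAL)
        total, per = subject_loglik(FIXTURE_PARAMS, data)
        oracle_total, oracle_per = naive_loglik(FIXTURE_PARAMS, data)
        assert total == pytest.approx(oracle_total, abs=1e-10)
        np.testing.assert_allclose(per, oracle_per, atol=1e-10)
        assert total == pytest.approx(FIXTURE_LOGLIK, abs=1e-6)

    @pytest.mark.parametrize("variant", ["reward", "punishment",
                                         "protection", "direct_reward"])
    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_fuzz(self, variant, seed):
        rng = np.random.default_rng(seed)
        trials = [(int(rng.integers(2)), int(rng.integers(2)),
                   int(rng.integers(2)), int(rng.integers(10)))
                  for _ in range(5)]
        data = make_dataset(trials, variant=variant)
        params = AgentParams(omega=rng.uniform(), alpha=rng.uniform(),
                             lam=rng.uniform(), pi_stick=rng.uniform(),
                             beta=rng.uniform(0, 10))
        total, per = subject_loglik(params, data)
        oracle_total, oracle_per = naive_loglik(params, data)
        assert total == pytest.approx(oracle_total, abs=1e-10)
        np.testing.assert_allclose(per, oracle_per, atol=1e-10)

    def test_practice_trials_update_but_do_not_score(self):
        trials = [(0, 0, 0, 9), (0, 0, 0, 9), (0, 1, 0, 5)]
        data = make_dataset(trials, practice_flags=[True, True, False])
        params = AgentParams(omega=1.0, alpha=1.0, lam=1.0,
                             pi_stick=0.0, beta=1.0)
        total, per = subject_loglik(params, data)
        assert len(per) == 1
        # after practice, q2[creature 0] = 9: scored trial is not at 50/50
        assert total != pytest.approx(np.log(0.5), abs=1e-3)
        assert total == pytest.approx(naive_loglik(params, data)[0], abs=1e-10)

    def test_missed_trials_scored_zero_state_frozen(self):
        trials = [(0, 0, 0, 7), (1, 0, -1, -1), (0, 0, 0, 7)]
        data = make_dataset(trials)
        params = AgentParams(omega=0.4, alpha=0.6, lam=0.3,
                             pi_stick=0.2, beta=2.0)
        total, per = subject_loglik(params, data)
        assert per[1] == 0.0
        assert total == pytest.approx(naive_loglik(params, data)[0], abs=1e-10)

    def test_self_consistency_at_generating_params(self, basic_config):
        cfg = TaskConfig(variant="reward", n_trials=1000, n_practice=0)
        params = AgentParams(omega=0.6, alpha=0.5, lam=0.5,
                             pi_stick=0.1, beta=5.0)
        data, _ = simulate_subject(params, cfg, seed=123)
        ll_true, _ = subject_loglik(params, data)
        for dw in (-0.3, 0.3):
            w = params.resolve("omega", "reward", False) + dw
            perturbed = AgentParams(omega=w, alpha=0.5, lam=0.5,
                                    pi_stick=0.1, beta=5.0)
            assert ll_true >= subject_loglik(perturbed, data)[0]

    def test_position_relabeling_invariance_without_stickiness(self):
        trials = [(0, 0, 0, 7), (1, 1, 1, 2), (0, 1, 0, 5), (1, 0, 1, 8)]
        data = make_dataset(trials)
        flipped = make_dataset([(s, 1 - l, c, o) for s, l, c, o in trials])
        params = AgentParams(omega=0.5, alpha=0.5, lam=0.5,
                             pi_stick=0.0, beta=4.0)
        assert subject_loglik(params, data)[0] == pytest.approx(
            subject_loglik(params, flipped)[0], abs=1e-12)

    def test_out_of_range_outcome_rejected(self):
        data = make_dataset([(0, 0, 0, 5)])
        data.outcome_units[0] = 11
        with pytest.raises(ValueError, match="outside"):
            prepare_session(data)


class TestNegloglikSurface:
    def test_recovers_omega_one(self):
        cfg = TaskConfig(variant="reward", n_trials=600, n_practice=0)
        gen = AgentParams(omega=1.0, alpha=0.6, lam=0.6, pi_stick=0.0,
                          beta=8.0)
        data, _ = simulate_subject(gen, cfg, seed=21)
        grid = np.linspace(0.0, 1.0, 11)
        prof = negloglik_surface(data, grid, gen)
        assert grid[np.argmin(prof)] >= 0.9

    def test_flat_at_beta0(self):
        cfg = TaskConfig(variant="reward", n_trials=300, n_practice=0)
        gen = AgentParams(omega=0.5, beta=0.0)
        data, _ = simulate_subject(gen, cfg, seed=2)
        prof = negloglik_surface(data, np.linspace(0, 1, 5),
                                 AgentParams(omega=0.5, beta=0.0))
        assert np.ptp(prof) < 1e-9

    def test_length_one_grid(self):
        data = make_dataset([(0, 0, 0, 5)])
        prof = negloglik_surface(data, np.array([0.3]), AgentParams())
        assert prof.shape == (1,)


class TestPointwise:
    def test_validates_shape_and_sign(self):
        with pytest.raises(ValueError):
            PointwiseLogLik(np.zeros(3), "s", "M1")
        with pytest.raises(ValueError):
            PointwiseLogLik(np.full((2, 3), 0.5), "s", "M1")
        p = PointwiseLogLik(np.full((2, 3), -1.0), "s", "M1")
        assert p.values.shape == (2, 3)
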