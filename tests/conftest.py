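import numpy as np
import pytest

from twostep.agent import AgentParams, simulate_subject
from twostep.cohort import CohortScenario, generate_study
from twostep.task import TaskConfig, preset_configs


@pytest.fixture(scope="session")
def basic_config():
    return TaskConfig(variant="reward", n_trials=120, n_practice=20)


@pytest.fixture(scope="session")
def sim_dataset(basic_config):
    params = AgentParams(omega=0.6, alpha=0.5, lam=0.5, pi_stick=0.1, beta=5.0)
    data, internals = simulate_subject(params, basic_config, seed=42)
    return data, internals, params


@pytest.fixture(scope="session")
def small_cohort():
    """6-subject study-1-shaped synthetic cohort with ratings."""
    sc = CohortScenario(
        name="small", n_subjects=6, configs=preset_configs("study1"),
        omega={"protection": (0.7, 0.12), "reward": (0.3, 0.12)},
        alpha={v: (0.45, 0.15) for v in ("protection", "reward")})
    return generate_study(sc, seed=9)


def single_variant_cohort(omega, n_subjects=40, n_trials=150, beta=8.0,
                          seed=0, variant="reward", alpha=0.6, lam=0.6):
    """Homogeneous-parameter cohort on one variant (stay-signature tests)."""
    cfg = TaskConfig(variant=variant, n_trials=n_trials, n_practice=0)
    params = AgentParams(omega=omega, alpha=alpha, lam=lam,
                         pi_stick=0.0, beta=beta)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        data, _ = simulate_subject(params, cfg, seed=int(rng.integers(2**31)),
                                   subject_id=f"s{i:03d}")
        out.append(data)
    return out
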