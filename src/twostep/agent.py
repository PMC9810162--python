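"""Generative hybrid model-based / model-free learner.

Model-free values are learned SARSA(lambda)-style over the four first-stage
dwelling stimuli (2 states x 2 dwellings); model-based values are planned
through the deterministic transition map from the learned second-stage
creature values.  The two value sets are mixed by a weight ``omega`` and
fed to a softmax policy with inverse temperature ``beta`` and a stickiness
bonus ``pi_stick`` for repeating the previous response key.

Learning operates on the raw 0-9 outcome units, not the stakes-amplified
final result: stakes enter only as a possible parameter moderator.  For
the punishment framing the internal reward is reversed (9 - units) so
that "more is better" holds in every framing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import task as task_mod
from .data import MISSING, SubjectDataset
from .task import TaskConfig

Q_INIT = 4.5  # midpoint of the 0-9 payoff range; unbiased start


@dataclass
class AgentParams:
    """Five-parameter hybrid-learner parameterization.

    ``omega`` and ``alpha`` may be condition-split: either a scalar or a
    mapping from condition labels to values.  Recognized label forms, in
    lookup order: ``"{variant}:{low|high}"``, ``"{variant}"``,
    ``"{low|high}"``.  ``lam``, ``pi_stick`` and ``beta`` are always
    shared.
    """

    omega: float | dict[str, float] = 0.5
    alpha: float | dict[str, float] = 0.5
    lam: float = 0.5
    pi_stick: float = 0.0
    beta: float = 5.0

    def __post_init__(self) -> None:
        for name, val in (("lam", self.lam), ("pi_stick", self.pi_stick)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.beta <= 20.0:
            raise ValueError("beta must be in [0, 20]")
        for name in ("omega", "alpha"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(not 0.0 <= x <= 1.0 for x in vals):
                raise ValueError(f"{name} must be in [0, 1]")

    def resolve(self, name: str, variant: str, high_stakes: bool) -> float:
        """Look up omega or alpha for a trial's condition labels."""
        v = getattr(self, name)
        if not isinstance(v, dict):
            return v
        level = "high" if high_stakes else "low"
        for key in (f"{variant}:{level}", variant, level):
            if key in v:
                return v[key]
        raise KeyError(
            f"no {name} entry for variant={variant!r} stakes={level!r}; "
            f"have {sorted(v)}"
        )

    def to_dict(self) -> dict:
        return {
            "omega": self.omega, "alpha": self.alpha, "lam": self.lam,
            "pi_stick": self.pi_stick, "beta": self.beta,
        }


@dataclass
class AgentState:
    """Mutable learner state carried across trials of one session."""

    q_mf: np.ndarray = field(default_factory=lambda: np.full((2, 2), Q_INIT))
    q_stage2: np.ndarray = field(default_factory=lambda: np.full(2, Q_INIT))
    prev_key: int = MISSING  # response key (0=left, 1=right) of last response


def mb_values(state: int, q_stage2: np.ndarray,
              transition_map: np.ndarray) -> np.ndarray:
    """Planned values of the two dwellings: the visited creature's value."""
    return q_stage2[transition_map[state]]


def hybrid_values(q_mf_pair: np.ndarray, q_mb_pair: np.ndarray,
                  omega: float) -> np.ndarray:
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    return omega * np.asarray(q_mb_pair) + (1.0 - omega) * np.asarray(q_mf_pair)


def choice_probability(values: np.ndarray, prev_key: int, left_dwelling: int,
                       beta: float, pi_stick: float) -> np.ndarray:
    """Softmax choice probabilities over the two dwellings.

    The stickiness bonus goes to the dwelling whose response key (given
    this trial's left/right layout) repeats the previous response; on the
    first trial (``prev_key == MISSING``) no bonus applies.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rep = np.zeros(2)
    if prev_key != MISSING:
        for d in (0, 1):
            key = 0 if d == left_dwelling else 1
            if key == prev_key:
                rep[d] = 1.0
    x = beta * (np.asarray(values, dtype=float) + pi_stick * rep)
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def internal_reward(variant: str, outcome_units: int) -> float:
    """Valence-aligned reward: larger is always better for the learner."""
    if not 0 <= outcome_units <= 9:
        raise ValueError("outcome_units outside [0, 9]")
    if variant == "punishment":
        return 9.0 - outcome_units
    return float(outcome_units)


def update_state(state: int, choice: int, creature: int, reward_internal: float,
                 alpha: float, lam: float, agent: AgentState,
                 response_key: int) -> AgentState:
    """Apply the two-stage temporal-difference update in place.

    First-stage: delta1 = Q2(creature) - Qmf(state, choice), scaled by
    alpha.  Second-stage: delta2 = r - Q2(creature) updates the creature
    value by alpha and transfers to the first stage by alpha * lambda.
    """
    if not 0.0 <= reward_internal <= 9.0:
        raise ValueError("reward_internal outside [0, 9]")
    delta1 = agent.q_stage2[creature] - agent.q_mf[state, choice]
    agent.q_mf[state, choice] += alpha * delta1
    delta2 = reward_internal - agent.q_stage2[creature]
    agent.q_stage2[creature] += alpha * delta2
    agent.q_mf[state, choice] += alpha * lam * delta2
    agent.prev_key = response_key
    return agent


def simulate_subject(params: AgentParams, config: TaskConfig, seed: int,
                     subject_id: str = "sim") -> tuple[SubjectDataset, dict]:
    """Simulate one full session; deterministic given ``seed``.

    Returns the dataset and an internals dict with per-trial model
    quantities (``q2_visited``, ``value_gap``) used by the synthetic
    rating generator.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC401CE)))
    walks = task_mod.init_payoff_walks(config, seed)
    n = config.n_trials
    hi_stake = config.stakes_values[1]

    cols = {name: np.full(n, MISSING, dtype=np.int64) for name in (
        "stakes", "state", "left_dwelling", "choice", "response_key",
        "creature", "outcome_units", "final_result", "certainty",
        "outcome_estimate")}
    probe = np.full(n, task_mod.PROBE_NONE, dtype=np.int64)
    probe[config.n_practice:] = task_mod.make_probe_schedule(
        config.n_analyzable, rng, config.certainty_frac, config.estimate_frac)
    q2_visited = np.full(n, np.nan)
    value_gap = np.full(n, np.nan)

    agent = AgentState()
    for t in range(n):
        stakes = task_mod.draw_stakes(config, rng)
        state = int(rng.integers(2))
        left = int(rng.integers(2))
        cols["stakes"][t] = stakes
        cols["state"][t] = state
        cols["left_dwelling"][t] = left
        if config.miss_prob > 0 and rng.random() < config.miss_prob:
            continue  # missed trial: no choice, agent state frozen
        omega = params.resolve("omega", config.variant, stakes == hi_stake)
        alpha = params.resolve("alpha", config.variant, stakes == hi_stake)
        q_mb = mb_values(state, agent.q_stage2, config.transition_map)
        values = hybrid_values(agent.q_mf[state], q_mb, omega)
        p = choice_probability(values, agent.prev_key, left,
                               params.beta, params.pi_stick)
        choice = int(rng.random() < p[1])
        key = 0 if choice == left else 1
        creature = int(config.transition_map[state, choice])
        outcome = int(np.clip(round(walks.values[t, creature]), 0, 9))
        result = task_mod.final_result(config.variant, stakes, outcome,
                                       config.base_threat)
        cols["choice"][t] = choice
        cols["response_key"][t] = key
        cols["creature"][t] = creature
        cols["outcome_units"][t] = outcome
        cols["final_result"][t] = result  # magnitude; sign = result_sign(variant)
        value_gap[t] = abs(values[0] - values[1])
        q2_visited[t] = agent.q_stage2[creature]
        update_state(state, choice, creature,
                     internal_reward(config.variant, outcome),
                     alpha, params.lam, agent, key)

    data = SubjectDataset(
        subject_id=subject_id, variant=config.variant,
        trial_index=np.arange(n, dtype=np.int64),
        practice=np.arange(n) < config.n_practice,
        transition_map=np.asarray(config.transition_map),
        **cols,
    )
    internals = {
        "walks": walks, "probe": probe,
        "q2_visited": q2_visited, "value_gap": value_gap,
    }
    return data, internals
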