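"""Trial-wise choice log-likelihood of the hybrid learner.

The hot path (:func:`session_loglik_core`) is numba-compiled and operates
on flat arrays so the hierarchical sampler can evaluate it hundreds of
thousands of times.  Practice trials drive learner-state updates but are
never scored, so the likelihood of the first analyzable trials conditions
on the practice history the subject actually experienced; missed trials
contribute zero log-likelihood and freeze the agent state (including the
previous-response memory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .agent import Q_INIT, AgentParams, internal_reward
from .data import SubjectDataset


@dataclass
class SessionArrays:
    """One session's trials, flattened for the fast kernel.

    Practice trials are kept (they train the learner) but carry
    ``scored == 0`` so they never enter the likelihood.
    """

    variant: str
    state: np.ndarray        # int64
    choice: np.ndarray       # int64, -1 = missed
    left_dwelling: np.ndarray
    creature: np.ndarray
    reward: np.ndarray       # float64 internal (valence-aligned) reward
    stakes_high: np.ndarray  # int64 0/1
    scored: np.ndarray       # int64 0/1, non-practice trials
    transition_map: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.state)

    @property
    def scored_mask(self) -> np.ndarray:
        """Analyzable trials (practice excluded, missed included)."""
        return self.scored == 1

    @property
    def n_scored(self) -> int:
        """Analyzable non-missed trials."""
        return int(np.sum(self.scored_mask & (self.choice >= 0)))


def prepare_session(data: SubjectDataset) -> SessionArrays:
    """Precompute kernel inputs for all trials of one session."""
    out = data.outcome_units
    resp = data.choice >= 0
    if np.any((out[resp] < 0) | (out[resp] > 9)):
        raise ValueError("outcome_units outside [0, 9]")
    reward = np.zeros(len(data))
    reward[resp] = [internal_reward(data.variant, int(o)) for o in out[resp]]
    hi = int(np.max(data.stakes)) if len(data) else 5
    return SessionArrays(
        variant=data.variant,
        state=data.state.astype(np.int64),
        choice=data.choice.astype(np.int64),
        left_dwelling=data.left_dwelling.astype(np.int64),
        creature=data.creature.astype(np.int64),
        reward=reward,
        stakes_high=(data.stakes == hi).astype(np.int64),
        scored=data.analyzable.astype(np.int64),
        transition_map=np.asarray(data.transition_map, dtype=np.int64),
    )


@njit(fastmath=False)
def session_loglik_core(state, choice, left, creature, reward, cond, scored,
                        omega_c, alpha_c, lam, pi_stick, beta, tmap, q_init):
    """Per-trial log p(observed choice); practice and missed trials score 0."""
    n = state.shape[0]
    out = np.zeros(n)
    q_mf = np.full((2, 2), q_init)
    q2 = np.full(2, q_init)
    prev_key = -1
    for t in range(n):
        ch = choice[t]
        if ch < 0:
            continue
        s = state[t]
        c = cond[t]
        w = omega_c[c]
        a = alpha_c[c]
        l = left[t]
        if scored[t] == 1:
            v0 = w * q2[tmap[s, 0]] + (1.0 - w) * q_mf[s, 0]
            v1 = w * q2[tmap[s, 1]] + (1.0 - w) * q_mf[s, 1]
            if prev_key >= 0:
                key0 = 0 if l == 0 else 1
                if key0 == prev_key:
                    v0 += pi_stick
                else:
                    v1 += pi_stick
            x0 = beta * v0
            x1 = beta * v1
            m = x0 if x0 > x1 else x1
            lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m))
            out[t] = (x0 if ch == 0 else x1) - lse
        cr = creature[t]
        d1 = q2[cr] - q_mf[s, ch]
        q_mf[s, ch] += a * d1
        d2 = reward[t] - q2[cr]
        q2[cr] += a * d2
        q_mf[s, ch] += a * lam * d2
        prev_key = 0 if ch == l else 1
    return out


def _cond_arrays(params: AgentParams, sess: SessionArrays
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve possibly condition-split omega/alpha into per-trial indices."""
    omega_lo = params.resolve("omega", sess.variant, False)
    omega_hi = params.resolve("omega", sess.variant, True)
    alpha_lo = params.resolve("alpha", sess.variant, False)
    alpha_hi = params.resolve("alpha", sess.variant, True)
    omega_c = np.array([omega_lo, omega_hi])
    alpha_c = np.array([alpha_lo, alpha_hi])
    return sess.stakes_high, omega_c, alpha_c


def session_loglik(params: AgentParams, sess: SessionArrays,
                   q_init: float = Q_INIT) -> np.ndarray:
    cond, omega_c, alpha_c = _cond_arrays(params, sess)
    return session_loglik_core(
        sess.state, sess.choice, sess.left_dwelling, sess.creature,
        sess.reward, cond, sess.scored, omega_c, alpha_c,
        float(params.lam), float(params.pi_stick), float(params.beta),
        sess.transition_map, q_init)


def subject_loglik(params: AgentParams, data: SubjectDataset
                   ) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood over the analyzable trials.

    The returned vector has one entry per analyzable (non-practice)
    trial; missed trials appear as exact zeros.
    """
    sess = prepare_session(data)
    per_trial = session_loglik(params, sess)[sess.scored_mask]
    return float(per_trial.sum()), per_trial


def negloglik_surface(data: SubjectDataset, omega_grid: np.ndarray,
                      params: AgentParams) -> np.ndarray:
    """Profile of -loglik across an omega grid, other parameters fixed."""
    sess = prepare_session(data)
    out = np.empty(len(omega_grid))
    for i, w in enumerate(np.asarray(omega_grid, dtype=float)):
        p = AgentParams(omega=float(w), alpha=params.alpha, lam=params.lam,
                        pi_stick=params.pi_stick, beta=params.beta)
        out[i] = -session_loglik(p, sess).sum()
    return out


@dataclass
class PointwiseLogLik:
    """[posterior draw x trial] log-likelihood matrix for one subject."""

    values: np.ndarray
    subject_id: str
    model_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be [draws, trials]")
        if np.any(self.values > 1e-12):
            raise ValueError("log probabilities must be <= 0")
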