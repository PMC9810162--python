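"""Two-step stakes task environment.

The task has two first-stage states, each offering a choice between two
dwellings.  Transitions are deterministic: within each state one dwelling
leads to one of two second-stage creatures and the other dwelling to the
remaining creature, and the mapping is complementary across states so that
both creatures are reachable from either state.  Each creature pays out
0-9 units that drift over trials as an independent Gaussian random walk
with reflecting bounds.  Every trial carries a stakes amplifier (x1 or x5)
applied to the outcome and to the maximum result at risk.

Four framings share this structure and differ only in how the outcome
units map onto the final result:

* ``protection``    - units shield against a (9 x stakes) loss
* ``reward``        - units convert to gains via an intermediate token
* ``direct_reward`` - units are gains delivered directly
* ``punishment``    - units are losses delivered directly
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

VARIANTS = ("protection", "reward", "direct_reward", "punishment")

#: Framings where the final result is a loss (flames received).
AVERSIVE_VARIANTS = ("protection", "punishment")

# probe labels
PROBE_NONE = 0
PROBE_CERTAINTY = 1
PROBE_ESTIMATE = 2

#: Default deterministic transition table T[state, dwelling] -> creature.
#: Complementary across states: creature 0 is reached by dwelling 0 in
#: state 0 but by dwelling 1 in state 1.
DEFAULT_TRANSITIONS = np.array([[0, 1], [1, 0]], dtype=np.int64)


class ConfigError(ValueError):
    """Raised for invalid task configurations."""


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of one task arm (one variant for one study)."""

    variant: str = "protection"
    n_trials: int = 120
    n_practice: int = 20
    stakes_values: tuple[int, int] = (1, 5)
    stakes_prob: float = 0.5
    walk_sigma: float = 2.0
    walk_bounds: tuple[float, float] = (0.0, 9.0)
    init_ranges: tuple[tuple[int, int], tuple[int, int]] = ((0, 4), (5, 9))
    base_threat: int = 9
    transition_map: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    certainty_frac: float = 0.25
    estimate_frac: float = 0.25
    miss_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.n_trials <= 0 or not (0 <= self.n_practice < self.n_trials):
            raise ConfigError("need 0 <= n_practice < n_trials")
        lo_stake, hi_stake = self.stakes_values
        if not (0 < lo_stake < hi_stake):
            raise ConfigError("stakes_values must be increasing positive")
        lo, hi = self.walk_bounds
        if not lo < hi:
            raise ConfigError("walk_bounds must satisfy lo < hi")
        if self.walk_sigma < 0:
            raise ConfigError("walk_sigma must be non-negative")
        (a0, a1), (b0, b1) = self.init_ranges
        if not (lo <= a0 <= a1 < b0 <= b1 <= hi):
            raise ConfigError(
                "init_ranges must be disjoint, ordered and inside walk_bounds"
            )
        tm = np.asarray(self.transition_map)
        if tm.shape != (2, 2) or not all(set(tm[s]) == {0, 1} for s in (0, 1)):
            raise ConfigError("transition_map must map each state onto both creatures")
        if self.certainty_frac + self.estimate_frac > 1.0:
            raise ConfigError("probe fractions exceed 1")

    @property
    def n_analyzable(self) -> int:
        return self.n_trials - self.n_practice

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition_map"] = np.asarray(self.transition_map).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "transition_map" in d:
            d["transition_map"] = np.asarray(d["transition_map"], dtype=np.int64)
        for key in ("stakes_values", "walk_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        if "init_ranges" in d:
            d["init_ranges"] = tuple(tuple(r) for r in d["init_ranges"])
        return cls(**d)


#: Study scenario arms.  Study 1 used 120 trials (20 practice); Studies 2-3
#: used 225 trials (25 practice).
_PRESET_LENGTHS = {"study1": (120, 20), "study2": (225, 25), "study3": (225, 25)}
_PRESET_VARIANTS = {
    "study1": ("protection", "reward"),
    "study2": ("protection", "direct_reward"),
    "study3": ("protection", "punishment"),
}


def preset_configs(study: str, **overrides) -> dict[str, TaskConfig]:
    """Return the per-variant :class:`TaskConfig` pair for a study preset."""
    try:
        n_trials, n_practice = _PRESET_LENGTHS[study]
        variants = _PRESET_VARIANTS[study]
    except KeyError:
        raise ConfigError(
            f"unknown study preset {study!r}; expected one of {sorted(_PRESET_LENGTHS)}"
        ) from None
    return {
        v: TaskConfig(variant=v, n_trials=n_trials, n_practice=n_practice, **overrides)
        for v in variants
    }


def step_walk(value: float, sigma: float, rng: np.random.Generator,
              bounds: tuple[float, float] = (0.0, 9.0)) -> float:
    """Advance one random-walk payoff by a Gaussian step with reflection.

    Excursions past a bound are mirror-folded back inside, repeatedly if
    the step overshoots by more than the full range.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return reflect(value + rng.normal(0.0, sigma), *bounds)


def reflect(v: float, lo: float, hi: float) -> float:
    """Mirror-fold ``v`` into [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    width = hi - lo
    # period of the folded map is 2*width
    v = (v - lo) % (2.0 * width)
    if v > width:
        v = 2.0 * width - v
    return v + lo


@dataclass
class PayoffWalkSet:
    """Per-creature drifting payoff trajectories for one session."""

    values: np.ndarray  # [n_trials, 2]
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be [n_trials, 2]")


def init_payoff_walks(config: TaskConfig, seed: int) -> PayoffWalkSet:
    """Generate the full payoff-walk matrix for a session.

    One creature starts in the low initial range, the other in the high
    range (which creature is which is randomized), then each walks
    independently with reflecting bounds.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.walk_bounds
    (l0, l1), (h0, h1) = config.init_ranges
    vals = np.empty((config.n_trials, 2), dtype=float)
    low_first = rng.random() < 0.5
    low_init = rng.uniform(l0, l1)
    high_init = rng.uniform(h0, h1)
    vals[0] = (low_init, high_init) if low_first else (high_init, low_init)
    for t in range(1, config.n_trials):
        for c in (0, 1):
            vals[t, c] = step_walk(vals[t - 1, c], config.walk_sigma, rng, (lo, hi))
    return PayoffWalkSet(values=vals, seed=seed)


def draw_stakes(config: TaskConfig, rng: np.random.Generator) -> int:
    """Draw the trial's stakes amplifier (high with ``stakes_prob``)."""
    lo, hi = config.stakes_values
    return hi if rng.random() < config.stakes_prob else lo


def final_result(variant: str, stakes: int, outcome_units: int,
                 base_threat: int = 9) -> int:
    """Map delivered outcome units to the trial's final result.

    Returns the magnitude of the result: flames received for aversive
    variants (a loss), points gained otherwise.  Protection shields
    subtract from the stakes-amplified threat, e.g. 2 shields at x5
    against a 9-flame threat leave 45 - 10 = 35 flames.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if not 0 <= outcome_units <= base_threat:
        raise ValueError(f"outcome_units {outcome_units} outside [0, {base_threat}]")
    if variant == "protection":
        return (base_threat - outcome_units) * stakes
    if variant == "punishment":
        return outcome_units * stakes
    return outcome_units * stakes  # reward, direct_reward


def result_sign(variant: str) -> int:
    """Signed direction of the final result for bonus accounting."""
    return -1 if variant in AVERSIVE_VARIANTS else 1


def make_probe_schedule(n_trials: int, rng: np.random.Generator,
                        certainty_frac: float = 0.25,
                        estimate_frac: float = 0.25) -> np.ndarray:
    """Assign disjoint certainty / outcome-estimate probes to trials.

    Exact-count scheduling: ``round(frac * n)`` trials get each probe
    type, placed by a random permutation so the two sets never overlap.
    """
    if n_trials < 4:
        raise ValueError("need at least 4 trials to schedule probes")
    n_cert = round(certainty_frac * n_trials)
    n_est = round(estimate_frac * n_trials)
    if n_cert + n_est > n_trials:
        raise ValueError("probe fractions exceed 1")
    order = rng.permutation(n_trials)
    labels = np.full(n_trials, PROBE_NONE, dtype=np.int64)
    labels[order[:n_cert]] = PROBE_CERTAINTY
    labels[order[n_cert:n_cert + n_est]] = PROBE_ESTIMATE
    return labels
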