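"""Synthetic study generation.

A :class:`CohortScenario` fixes the task configuration pair, the group-
level natural-scale moments of every learner parameter, and the rating
generator.  Subject parameters are sampled on the latent (logit) scale
with latent moments chosen by moment matching, so a generated cohort is
exactly the population the hierarchical model assumes - which makes
parameter-recovery tests fair.

The probe-rating generator is synthetic plumbing (no generative model
for ratings exists in the source analyses): outcome estimates are an
affine function of either the learner's expected payoff of the visited
creature (``basis="expected"``) or the realized outcome
(``basis="outcome"``), and certainty is an affine function of the
absolute hybrid value difference at choice time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .agent import AgentParams, simulate_subject
from .data import MISSING, SubjectDataset
from .task import (PROBE_CERTAINTY, PROBE_ESTIMATE, TaskConfig,
                   preset_configs)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class RatingParams:
    """Synthetic probe-rating generator settings (not from the source)."""

    slope_mean: float = 0.6
    slope_sd: float = 0.2
    intercept: float = 1.0
    noise_sd: float = 1.0
    basis: str = "expected"      # "expected" (model's Q) or "outcome"
    cert_intercept: float = 2.0
    cert_gain: float = 1.5
    cert_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.basis not in ("expected", "outcome"):
            raise ScenarioError("basis must be 'expected' or 'outcome'")


@dataclass(frozen=True)
class CohortScenario:
    name: str
    n_subjects: int
    configs: dict[str, TaskConfig]          # variant -> config
    omega: dict[str, tuple[float, float]]   # variant -> (mean, sd)
    alpha: dict[str, tuple[float, float]]
    lam: tuple[float, float] = (0.5, 0.15)
    pi_stick: tuple[float, float] = (0.1, 0.05)
    beta: tuple[float, float] = (5.0, 1.5)
    ratings: RatingParams = field(default_factory=RatingParams)
    #: draw one omega/alpha per subject shared by all variants (an
    #: M1-consistent population); requires identical moments per variant
    share_across_variants: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ScenarioError("n_subjects must be positive")
        for name, table in (("omega", self.omega), ("alpha", self.alpha)):
            if set(table) != set(self.configs):
                raise ScenarioError(f"{name} moments must cover every variant")
            for variant, (m, s) in table.items():
                if not 0 < m < 1 or s < 0:
                    raise ScenarioError(
                        f"{name}[{variant}] mean must be in (0,1), sd >= 0")
        for name, (m, s) in (("lam", self.lam), ("pi_stick", self.pi_stick)):
            if not 0 < m < 1 or s < 0:
                raise ScenarioError(f"{name} mean must be in (0,1), sd >= 0")
        m, s = self.beta
        if not 0 < m < 20 or s < 0:
            raise ScenarioError("beta mean must be in (0,20), sd >= 0")

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(self.configs)


#: Group means (SDs) of omega and alpha per variant, per study, as
#: reported for the best-fitting variant-split model.  lam/pi/beta group
#: values are synthetic defaults (not printed in the source text).
_PRESET_MOMENTS = {
    "study1": {"omega": {"protection": (0.72, 0.14), "reward": (0.14, 0.22)},
               "alpha": {"protection": (0.47, 0.33), "reward": (0.43, 0.32)}},
    "study2": {"omega": {"protection": (0.76, 0.18),
                         "direct_reward": (0.55, 0.25)},
               "alpha": {"protection": (0.48, 0.35),
                         "direct_reward": (0.51, 0.37)}},
    "study3": {"omega": {"protection": (0.74, 0.14),
                         "punishment": (0.54, 0.25)},
               "alpha": {"protection": (0.58, 0.35),
                         "punishment": (0.51, 0.37)}},
}


def preset_scenario(study: str, n_subjects: int = 200,
                    **overrides) -> CohortScenario:
    if study not in _PRESET_MOMENTS:
        raise ScenarioError(f"unknown scenario preset {study!r}")
    kw = dict(name=study, n_subjects=n_subjects,
              configs=preset_configs(study), **_PRESET_MOMENTS[study])
    kw.update(overrides)
    return CohortScenario(**kw)


# ---------------------------------------------------------------------------
# latent moment matching

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(61)


def _natural_moments(mu: float, sigma: float, scale: float) -> tuple[float, float]:
    """Mean and SD of scale*sigmoid(N(mu, sigma^2)) by Gauss-Hermite."""
    x = mu + np.sqrt(2.0) * sigma * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    f = scale * expit(x)
    m = float(w @ f)
    v = float(w @ (f - m) ** 2)
    return m, float(np.sqrt(max(v, 0.0)))


def match_latent_moments(mean: float, sd: float, scale: float = 1.0,
                         label: str = "", tol: float = 5e-3
                         ) -> tuple[float, float]:
    """Latent (mu, sigma) whose sigmoid-transformed moments hit the target.

    Raises :class:`ScenarioError` when the requested SD is unreachable for
    the requested mean (the transform bounds the variance).
    """
    if not 0 < mean < scale:
        raise ScenarioError(f"{label or 'parameter'}: mean {mean} outside "
                            f"(0, {scale})")
    mu0 = float(logit(mean / scale))
    if sd == 0:
        return mu0, 0.0

    def loss(v):
        m, s = _natural_moments(v[0], np.exp(v[1]), scale)
        return ((m - mean) / scale) ** 2 + ((s - sd) / scale) ** 2

    best = None
    for ls0 in (-1.0, 0.0, 1.0):
        r = minimize(loss, np.array([mu0, ls0]), method="Nelder-Mead",
                     options={"xatol": 1e-8, "fatol": 1e-14,
                              "maxiter": 2000})
        if best is None or r.fun < best.fun:
            best = r
    mu, sigma = float(best.x[0]), float(np.exp(best.x[1]))
    m, s = _natural_moments(mu, sigma, scale)
    if abs(m - mean) / scale > tol or abs(s - sd) / scale > tol:
        raise ScenarioError(
            f"{label or 'parameter'}: target mean {mean}, sd {sd} not "
            f"attainable under the sigmoid transform (best: {m:.3f}, {s:.3f})")
    return mu, sigma


def sample_cohort_params(scenario: CohortScenario,
                         rng: np.random.Generator) -> list[AgentParams]:
    """Draw per-subject parameters matching the scenario's moments."""
    latents = {}
    for name in ("omega", "alpha"):
        for variant, (m, s) in getattr(scenario, name).items():
            latents[(name, variant)] = match_latent_moments(
                m, s, 1.0, f"{name}[{variant}]")
    latents[("lam", None)] = match_latent_moments(*scenario.lam, 1.0, "lam")
    latents[("pi_stick", None)] = match_latent_moments(
        *scenario.pi_stick, 1.0, "pi_stick")
    latents[("beta", None)] = match_latent_moments(
        *scenario.beta, 20.0, "beta")

    def draw(key, scale=1.0):
        mu, sigma = latents[key]
        return float(scale * expit(mu + sigma * rng.standard_normal()))

    if scenario.share_across_variants:
        for name in ("omega", "alpha"):
            if len({getattr(scenario, name)[v]
                    for v in scenario.variants}) > 1:
                raise ScenarioError(
                    f"share_across_variants requires identical {name} "
                    "moments for every variant")

    out = []
    first = scenario.variants[0]
    for _ in range(scenario.n_subjects):
        if scenario.share_across_variants:
            w, a = draw(("omega", first)), draw(("alpha", first))
            omega = {v: w for v in scenario.variants}
            alpha = {v: a for v in scenario.variants}
        else:
            omega = {v: draw(("omega", v)) for v in scenario.variants}
            alpha = {v: draw(("alpha", v)) for v in scenario.variants}
        out.append(AgentParams(
            omega=omega,
            alpha=alpha,
            lam=draw(("lam", None)),
            pi_stick=draw(("pi_stick", None)),
            beta=draw(("beta", None), 20.0),
        ))
    return out


# ---------------------------------------------------------------------------
# study generation


def generate_ratings(data: SubjectDataset, internals: dict,
                     rp: RatingParams, subject_slope: float,
                     rng: np.random.Generator) -> None:
    """Fill the probe rating columns of one simulated session in place."""
    probe = internals["probe"]
    for t in range(len(data)):
        if data.choice[t] == MISSING:
            continue
        if probe[t] == PROBE_ESTIMATE:
            basis = (float(data.outcome_units[t]) if rp.basis == "outcome"
                     else float(internals["q2_visited"][t]))
            val = (subject_slope * basis + rp.intercept
                   + rng.normal(0.0, rp.noise_sd))
            data.outcome_estimate[t] = int(np.clip(round(val), 0, 9))
        elif probe[t] == PROBE_CERTAINTY:
            val = (rp.cert_intercept
                   + rp.cert_gain * float(internals["value_gap"][t])
                   + rng.normal(0.0, rp.cert_noise_sd))
            data.certainty[t] = int(np.clip(round(val), 0, 9))


@dataclass
class Subject:
    subject_id: str
    params: AgentParams
    rating_slope: float
    order: tuple[str, ...]                  # variant presentation order
    datasets: dict[str, SubjectDataset]
    internals: dict[str, dict]


@dataclass
class Cohort:
    scenario: CohortScenario
    seed: int
    subjects: list[Subject]

    def datasets_by_subject(self) -> dict[str, list[SubjectDataset]]:
        return {s.subject_id: [s.datasets[v] for v in s.order]
                for s in self.subjects}

    def all_datasets(self) -> list[SubjectDataset]:
        return [d for s in self.subjects for d in s.datasets.values()]

    def true_param_table(self):
        import pandas as pd
        rows = []
        for s in self.subjects:
            for v in self.scenario.variants:
                rows.append({
                    "subject_id": s.subject_id, "variant": v,
                    "omega": s.params.resolve("omega", v, False),
                    "alpha": s.params.resolve("alpha", v, False),
                    "lam": s.params.lam, "pi_stick": s.params.pi_stick,
                    "beta": s.params.beta,
                })
        return pd.DataFrame(rows)


def generate_study(scenario: CohortScenario, seed: int) -> Cohort:
    """Simulate a full synthetic study, counterbalancing variant order."""
    root = np.random.SeedSequence((seed, 0xC0F0))
    param_rng = np.random.default_rng(root.spawn(1)[0])
    params = sample_cohort_params(scenario, param_rng)
    slopes = (scenario.ratings.slope_mean
              + scenario.ratings.slope_sd
              * param_rng.standard_normal(scenario.n_subjects))
    variants = list(scenario.variants)
    subjects = []
    width = len(str(scenario.n_subjects - 1))
    for i, ss in enumerate(root.spawn(scenario.n_subjects + 1)[1:]):
        sid = f"sub{i:0{width}d}"
        order = tuple(variants if i % 2 == 0 else variants[::-1])
        child = ss.generate_state(2)
        rating_rng = np.random.default_rng(ss.spawn(1)[0])
        datasets, internals = {}, {}
        for k, v in enumerate(order):
            data, info = simulate_subject(
                params[i], scenario.configs[v],
                seed=int(child[k]), subject_id=sid)
            generate_ratings(data, info, scenario.ratings,
                             float(slopes[i]), rating_rng)
            datasets[v] = data
            internals[v] = info
        subjects.append(Subject(subject_id=sid, params=params[i],
                                rating_slope=float(slopes[i]), order=order,
                                datasets=datasets, internals=internals))
    return Cohort(scenario=scenario, seed=seed, subjects=subjects)
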