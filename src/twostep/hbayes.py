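"""Hierarchical Bayesian estimation of the hybrid-learner models M1-M4.

Each subject-level parameter is non-centered: theta_subject =
mu_group + sigma_group * eps_subject, with standard-normal priors on
mu_group, sigma_group (lower-bounded at zero, i.e. half-normal via
sigma = |sigma_raw|) and eps_subject.  Latent parameters map to their
natural scale by a logistic sigmoid ([0, 1] for omega, alpha, lambda,
pi) scaled by 20 for the inverse temperature beta.

Sampling uses an adaptive Metropolis-within-Gibbs scheme on the
unconstrained parameters: a joint random-walk block per subject over its
offsets, scalar random walks on the group means and SDs, and
likelihood-free interweaving moves (re-centering mu / rescaling sigma
while holding every subject's latent value fixed) that restore group-
level mixing when the per-subject data are informative.  The likelihood
is evaluated for the whole cohort in a single numba kernel call, so the
contract "any sampler meeting the recovery properties" is met at desk
scale without a gradient backend.

Models M1-M4 differ only in how omega and alpha are tied across the two
task variants and the two stakes levels; lambda, pi and beta are always
shared within subject.  Both variants of a study are fit jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .agent import Q_INIT
from .data import SubjectDataset
from .likelihood import prepare_session

MODEL_IDS = ("M1", "M2", "M3", "M4")

_SPLITS = {
    "M1": (False, False),
    "M2": (False, True),
    "M3": (True, False),
    "M4": (True, True),
}


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Parameter-tying scheme: which conditions get their own omega/alpha."""

    model_id: str
    variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if not 1 <= len(self.variants) <= 2:
            raise ValueError("expected one or two task variants")

    @property
    def split_variant(self) -> bool:
        return _SPLITS[self.model_id][0]

    @property
    def split_stakes(self) -> bool:
        return _SPLITS[self.model_id][1]

    @property
    def conditions(self) -> tuple[str, ...]:
        """Labels of the omega/alpha conditions, in index order."""
        if self.split_variant and self.split_stakes:
            return tuple(f"{v}:{s}" for v in self.variants
                         for s in ("low", "high"))
        if self.split_variant:
            return tuple(self.variants)
        if self.split_stakes:
            return ("low", "high")
        return ("shared",)

    @property
    def n_cond(self) -> int:
        return len(self.conditions)

    @property
    def n_free(self) -> int:
        """Free natural parameters per subject (omegas + alphas + 3)."""
        return 2 * self.n_cond + 3

    @property
    def param_names(self) -> tuple[str, ...]:
        return (tuple(f"omega[{c}]" for c in self.conditions)
                + tuple(f"alpha[{c}]" for c in self.conditions)
                + ("lam", "pi_stick", "beta"))

    @property
    def param_kinds(self) -> tuple[str, ...]:
        return ("unit",) * (2 * self.n_cond + 2) + ("beta",)

    def cond_index(self, variant: str, stakes_high: bool) -> int:
        if variant not in self.variants:
            raise FitError(f"variant {variant!r} not in spec {self.variants}")
        vi = self.variants.index(variant)
        if self.split_variant and self.split_stakes:
            return 2 * vi + int(stakes_high)
        if self.split_variant:
            return vi
        if self.split_stakes:
            return int(stakes_high)
        return 0


def transform_to_natural(theta_raw, kind: str):
    """Latent-to-natural map: sigmoid, scaled by 20 for beta."""
    if kind == "beta":
        return 20.0 * expit(theta_raw)
    if kind == "unit":
        return expit(theta_raw)
    raise ValueError(f"unknown parameter kind {kind!r}")


# ---------------------------------------------------------------------------
# flattened cohort likelihood


@njit(fastmath=False)
def _cohort_ll(ptr, sess_subj, state, choice, left, creature, reward, cond,
               scored, tmap, omega, alpha, lam, pi_stick, beta, q_init,
               subject_ll, per_trial):
    subject_ll[:] = 0.0
    n_sess = ptr.shape[0] - 1
    for si in range(n_sess):
        j = sess_subj[si]
        q_mf = np.full((2, 2), q_init)
        q2 = np.full(2, q_init)
        prev_key = -1
        for t in range(ptr[si], ptr[si + 1]):
            ch = choice[t]
            if ch < 0:
                per_trial[t] = 0.0
                continue
            s = state[t]
            c = cond[t]
            w = omega[j, c]
            a = alpha[j, c]
            l = left[t]
            if scored[t] == 1:
                v0 = w * q2[tmap[s, 0]] + (1.0 - w) * q_mf[s, 0]
                v1 = w * q2[tmap[s, 1]] + (1.0 - w) * q_mf[s, 1]
                if prev_key >= 0:
                    if (0 if l == 0 else 1) == prev_key:
                        v0 += pi_stick[j]
                    else:
                        v1 += pi_stick[j]
                x0 = beta[j] * v0
                x1 = beta[j] * v1
                m = x0 if x0 > x1 else x1
                lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m))
                lp = (x0 if ch == 0 else x1) - lse
                per_trial[t] = lp
                subject_ll[j] += lp
            else:
                per_trial[t] = 0.0
            cr = creature[t]
            d1 = q2[cr] - q_mf[s, ch]
            q_mf[s, ch] += a * d1
            d2 = reward[t] - q2[cr]
            q2[cr] += a * d2
            q_mf[s, ch] += a * lam[j] * d2
            prev_key = 0 if ch == l else 1


@dataclass
class HierarchicalModel:
    """Joint density of one tying scheme over a cohort (both variants)."""

    spec: ModelSpec
    subject_ids: list[str]
    # flattened session arrays
    ptr: np.ndarray
    sess_subj: np.ndarray
    state: np.ndarray
    choice: np.ndarray
    left: np.ndarray
    creature: np.ndarray
    reward: np.ndarray
    cond: np.ndarray
    scored: np.ndarray
    tmap: np.ndarray
    q_init: float = Q_INIT
    _subject_ll_buf: np.ndarray = field(init=False, repr=False)
    _per_trial_buf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._subject_ll_buf = np.zeros(max(self.n_subjects, 1))
        self._per_trial_buf = np.zeros(max(len(self.state), 1))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    @property
    def scored_mask(self) -> np.ndarray:
        """Analyzable non-missed trials, flat order."""
        return (self.scored == 1) & (self.choice >= 0)

    def natural_params(self, theta_lat: np.ndarray) -> tuple:
        """Split latent [n_sub, K] into kernel-ready natural arrays."""
        C = self.spec.n_cond
        nat = expit(theta_lat)
        omega = np.ascontiguousarray(nat[:, :C])
        alpha = np.ascontiguousarray(nat[:, C:2 * C])
        lam = np.ascontiguousarray(nat[:, 2 * C])
        pi_stick = np.ascontiguousarray(nat[:, 2 * C + 1])
        beta = np.ascontiguousarray(20.0 * nat[:, 2 * C + 2])
        return omega, alpha, lam, pi_stick, beta

    def subject_logliks(self, theta_lat: np.ndarray) -> np.ndarray:
        """Per-subject total log-likelihood at latent values [n_sub, K]."""
        if self.n_subjects == 0:
            return np.zeros(0)
        omega, alpha, lam, pi, beta = self.natural_params(theta_lat)
        _cohort_ll(self.ptr, self.sess_subj, self.state, self.choice,
                   self.left, self.creature, self.reward, self.cond,
                   self.scored, self.tmap, omega, alpha, lam, pi, beta,
                   self.q_init, self._subject_ll_buf, self._per_trial_buf)
        return self._subject_ll_buf.copy()

    def pointwise_loglik(self, theta_lat: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihood (scored trials only, flat order)."""
        omega, alpha, lam, pi, beta = self.natural_params(theta_lat)
        _cohort_ll(self.ptr, self.sess_subj, self.state, self.choice,
                   self.left, self.creature, self.reward, self.cond,
                   self.scored, self.tmap, omega, alpha, lam, pi, beta,
                   self.q_init, self._subject_ll_buf, self._per_trial_buf)
        return self._per_trial_buf[self.scored_mask].copy()

    def log_density(self, mu: np.ndarray, sigma_raw: np.ndarray,
                    eps: np.ndarray) -> float:
        """Log prior + log likelihood (normalizing constants dropped)."""
        lp = -0.5 * (np.sum(mu ** 2) + np.sum(sigma_raw ** 2)
                     + np.sum(eps ** 2))
        if self.n_subjects:
            theta = mu[None, :] + np.abs(sigma_raw)[None, :] * eps
            lp += float(self.subject_logliks(theta).sum())
        return lp


def build_model(spec: ModelSpec,
                cohort: dict[str, list[SubjectDataset]]) -> HierarchicalModel:
    """Flatten a cohort (subject -> sessions) for the sampler.

    Every session's variant must appear in ``spec.variants``.  A
    zero-subject cohort yields a prior-only model.
    """
    subject_ids = sorted(cohort)
    ptr = [0]
    sess_subj, cols = [], {k: [] for k in
                           ("state", "choice", "left", "creature",
                            "reward", "cond", "scored")}
    tmap = None
    for j, sid in enumerate(subject_ids):
        sessions = cohort[sid]
        if not sessions:
            raise FitError(f"subject {sid} has no sessions")
        for ds in sessions:
            sess = prepare_session(ds)
            ci = np.array([spec.cond_index(sess.variant, bool(h))
                           for h in sess.stakes_high], dtype=np.int64)
            sess_subj.append(j)
            cols["state"].append(sess.state)
            cols["choice"].append(sess.choice)
            cols["left"].append(sess.left_dwelling)
            cols["creature"].append(sess.creature)
            cols["reward"].append(sess.reward)
            cols["cond"].append(ci)
            cols["scored"].append(sess.scored)
            ptr.append(ptr[-1] + sess.n_trials)
            tmap = sess.transition_map
    if tmap is None:
        tmap = np.array([[0, 1], [1, 0]], dtype=np.int64)
    flat = {k: (np.concatenate(v) if v else np.zeros(0, dtype=np.int64))
            for k, v in cols.items()}
    flat["reward"] = flat["reward"].astype(float)
    return HierarchicalModel(
        spec=spec, subject_ids=subject_ids,
        ptr=np.array(ptr, dtype=np.int64),
        sess_subj=np.array(sess_subj, dtype=np.int64),
        state=flat["state"], choice=flat["choice"], left=flat["left"],
        creature=flat["creature"], reward=flat["reward"], cond=flat["cond"],
        scored=flat["scored"], tmap=np.asarray(tmap, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# sampler

PRESETS = {
    # (chains, post-warmup samples, warmup)
    "paper": (4, 2000, 2000),  # "4 chains of 4000 samples", half warmup
    "desk": (2, 500, 500),     # scaled-down contract for CI / desk runs
}


@dataclass
class Posterior:
    """MCMC draws on both scales plus convergence diagnostics."""

    model: HierarchicalModel
    mu: np.ndarray          # [chains, draws, K]
    sigma: np.ndarray       # [chains, draws, K]
    theta_nat: np.ndarray   # [chains, thinned draws, n_sub, K] natural scale
    theta_lat: np.ndarray   # same shape, latent scale
    accept_rates: dict

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def rhat(self) -> dict[str, float]:
        """Split-R-hat of the group-level draws."""
        out = {}
        for name, arr in (("mu", self.mu), ("sigma", self.sigma)):
            for k, pname in enumerate(self.spec.param_names):
                out[f"{name}[{pname}]"] = _split_rhat(arr[:, :, k])
        return out

    def max_rhat(self) -> float:
        vals = [v for v in self.rhat().values() if np.isfinite(v)]
        return max(vals) if vals else np.nan

    def pointwise_loglik(self, max_draws: int = 500) -> np.ndarray:
        """[draws x scored trials] matrix over thinned posterior draws."""
        th = self.theta_lat.reshape(-1, *self.theta_lat.shape[2:])
        if len(th) > max_draws:
            idx = np.linspace(0, len(th) - 1, max_draws).astype(int)
            th = th[idx]
        return np.stack([self.model.pointwise_loglik(t) for t in th])


def _split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat for one scalar quantity, draws shaped [chains, n]."""
    chains, n = draws.shape
    if n < 4:
        return np.nan
    half = n // 2
    segs = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n2 = segs.shape
    var_w = segs.var(axis=1, ddof=1).mean()
    var_b = n2 * segs.mean(axis=1).var(ddof=1)
    if var_w <= 0:
        return np.nan
    var_plus = (n2 - 1) / n2 * var_w + var_b / n2
    return float(np.sqrt(var_plus / var_w))


def fit(model: HierarchicalModel, preset: str | None = "desk",
        chains: int | None = None, samples: int | None = None,
        warmup: int | None = None, seed: int = 0,
        theta_thin: int = 4, rhat_warn: float = 1.1,
        n_sweeps: int = 3) -> Posterior:
    """Run the adaptive MCMC sampler.

    ``samples`` counts post-warmup draws per chain.  ``n_sweeps`` inner
    update sweeps are performed per recorded draw (raising effective
    sample quality at fixed memory).  A split-R-hat above ``rhat_warn``
    triggers a warning, never a silent pass.
    """
    if preset is not None:
        c, s, w = PRESETS[preset]
        chains = chains or c
        samples = samples or s
        warmup = warmup if warmup is not None else w
    if not (chains and samples) or warmup is None:
        raise ValueError("need chains/samples/warmup or a preset")

    K, n_sub = model.n_free, model.n_subjects
    root = np.random.SeedSequence((seed, 0x5A3B1E))
    per_chain = []
    for chain, ss in enumerate(root.spawn(chains)):
        per_chain.append(_run_chain(model, ss, samples, warmup, theta_thin,
                                    n_sweeps))
    mu = np.stack([c["mu"] for c in per_chain])
    sigma = np.stack([c["sigma"] for c in per_chain])
    theta_nat = np.stack([c["theta_nat"] for c in per_chain])
    theta_lat = np.stack([c["theta_lat"] for c in per_chain])
    acc = {k: float(np.mean([c["acc"][k] for c in per_chain]))
           for k in per_chain[0]["acc"]}
    post = Posterior(model=model, mu=mu, sigma=sigma, theta_nat=theta_nat,
                     theta_lat=theta_lat, accept_rates=acc)
    worst = post.max_rhat()
    if np.isfinite(worst) and worst > rhat_warn:
        warnings.warn(
            f"split-R-hat {worst:.3f} exceeds {rhat_warn}; "
            "chains may not have converged", RuntimeWarning, stacklevel=2)
    return post


def _run_chain(model: HierarchicalModel, seedseq, samples: int, warmup: int,
               theta_thin: int, n_sweeps: int) -> dict:
    rng = np.random.default_rng(seedseq)
    K, n_sub = model.n_free, model.n_subjects
    mu = 0.1 * rng.standard_normal(K)
    sigma_raw = 0.5 + 0.1 * np.abs(rng.standard_normal(K))
    eps = 0.1 * rng.standard_normal((n_sub, K))

    def theta(mu, sigma_raw, eps):
        return mu[None, :] + np.abs(sigma_raw)[None, :] * eps

    ll = model.subject_logliks(theta(mu, sigma_raw, eps))

    s_eps = np.full(max(n_sub, 1), 0.25)
    s_mu = np.full(K, 0.2)
    s_sig = np.full(K, 0.2)
    s_mu_iw = np.full(K, 0.3)
    s_sig_iw = np.full(K, 0.3)
    acc_count = {"eps": 0.0, "mu": 0.0, "sigma": 0.0, "mu_iw": 0.0,
                 "sigma_iw": 0.0}
    n_count = {k: 0 for k in acc_count}

    out_mu = np.empty((samples, K))
    out_sigma = np.empty((samples, K))
    n_keep = (samples + theta_thin - 1) // theta_thin
    out_nat = np.empty((n_keep, n_sub, K))
    out_lat = np.empty((n_keep, n_sub, K))

    total_iters = warmup + samples
    gamma0 = 1.0
    for it in range(total_iters):
        adapting = it < warmup
        gamma = gamma0 / np.sqrt(1.0 + it) if adapting else 0.0
        for _ in range(n_sweeps):
            # --- subject offset blocks (vectorized, independent A/R) ---
            if n_sub:
                prop = eps + s_eps[:, None] * rng.standard_normal((n_sub, K))
                ll_prop = model.subject_logliks(theta(mu, sigma_raw, prop))
                logr = (ll_prop - ll
                        + 0.5 * (np.sum(eps ** 2, axis=1)
                                 - np.sum(prop ** 2, axis=1)))
                take = np.log(rng.random(n_sub)) < logr
                eps[take] = prop[take]
                ll[take] = ll_prop[take]
                if adapting:
                    s_eps *= np.exp(gamma * (take.astype(float) - 0.25))
                acc_count["eps"] += take.mean()
                n_count["eps"] += 1

            # --- group means and SDs, scalar random walks ---
            for arr, scales, name in ((mu, s_mu, "mu"),
                                      (sigma_raw, s_sig, "sigma")):
                for k in range(K):
                    old = arr[k]
                    arr[k] = old + scales[k] * rng.standard_normal()
                    ll_prop = model.subject_logliks(theta(mu, sigma_raw, eps))
                    logr = (ll_prop.sum() - ll.sum()
                            + 0.5 * (old ** 2 - arr[k] ** 2))
                    if np.log(rng.random()) < logr:
                        ll = ll_prop
                        acc_count[name] += 1
                        if adapting:
                            scales[k] *= np.exp(gamma * (1 - 0.44))
                    else:
                        arr[k] = old
                        if adapting:
                            scales[k] *= np.exp(gamma * (0 - 0.44))
                    n_count[name] += 1

            # --- interweaving moves: latent subject values held fixed ---
            if n_sub:
                for k in range(K):
                    # translate mu_k, absorb into eps; likelihood unchanged
                    new_mu = mu[k] + s_mu_iw[k] * rng.standard_normal()
                    sig = abs(sigma_raw[k])
                    if sig > 1e-12:
                        new_eps = eps[:, k] + (mu[k] - new_mu) / sig
                        logr = (0.5 * (mu[k] ** 2 - new_mu ** 2)
                                + 0.5 * (np.sum(eps[:, k] ** 2)
                                         - np.sum(new_eps ** 2)))
                        ok = np.log(rng.random()) < logr
                        if ok:
                            mu[k] = new_mu
                            eps[:, k] = new_eps
                        if adapting:
                            s_mu_iw[k] *= np.exp(gamma * (float(ok) - 0.44))
                        acc_count["mu_iw"] += float(ok)
                        n_count["mu_iw"] += 1
                    # rescale sigma_k, absorb into eps
                    new_sr = sigma_raw[k] + s_sig_iw[k] * rng.standard_normal()
                    new_sig = abs(new_sr)
                    if sig > 1e-12 and new_sig > 1e-12:
                        ratio = sig / new_sig
                        new_eps = eps[:, k] * ratio
                        logr = (0.5 * (sigma_raw[k] ** 2 - new_sr ** 2)
                                + 0.5 * (np.sum(eps[:, k] ** 2)
                                         - np.sum(new_eps ** 2))
                                + n_sub * np.log(ratio))
                        ok = np.log(rng.random()) < logr
                        if ok:
                            sigma_raw[k] = new_sr
                            eps[:, k] = new_eps
                        if adapting:
                            s_sig_iw[k] *= np.exp(gamma * (float(ok) - 0.44))
                        acc_count["sigma_iw"] += float(ok)
                        n_count["sigma_iw"] += 1

        if it >= warmup:
            i = it - warmup
            out_mu[i] = mu
            out_sigma[i] = np.abs(sigma_raw)
            if i % theta_thin == 0:
                th = theta(mu, sigma_raw, eps)
                out_lat[i // theta_thin] = th
                C = model.spec.n_cond
                nat = expit(th)
                nat[:, 2 * C + 2] *= 20.0
                out_nat[i // theta_thin] = nat

    acc = {k: acc_count[k] / max(n_count[k], 1) for k in acc_count}
    return {"mu": out_mu, "sigma": out_sigma, "theta_nat": out_nat,
            "theta_lat": out_lat, "acc": acc}


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PosteriorSummary:
    """Natural-scale posterior means with convergence diagnostics."""

    model_id: str
    subject_table: pd.DataFrame  # subject_id, parameter, condition, mean, sd
    group_table: pd.DataFrame    # parameter, condition, mean, sd across subjects
    rhat: dict[str, float]

    def subject_means(self, parameter: str, condition: str) -> pd.Series:
        t = self.subject_table
        sel = t[(t.parameter == parameter) & (t.condition == condition)]
        if sel.empty:
            raise KeyError(f"no entries for {parameter}[{condition}]")
        return sel.set_index("subject_id")["mean"]

    def to_csv(self, path) -> None:
        self.subject_table.to_csv(path, index=False)


def posterior_means(post: Posterior) -> PosteriorSummary:
    """Natural-scale posterior mean and SD per subject and parameter."""
    spec = post.spec
    nat = post.theta_nat.reshape(-1, *post.theta_nat.shape[2:])
    means = nat.mean(axis=0)  # [n_sub, K]
    sds = nat.std(axis=0, ddof=1) if len(nat) > 1 else np.zeros_like(means)
    rows = []
    names = spec.param_names
    conds = spec.conditions
    for j, sid in enumerate(post.model.subject_ids):
        for k, name in enumerate(names):
            if "[" in name:
                parameter, condition = name[:-1].split("[")
            else:
                parameter, condition = name, "shared"
            rows.append({"subject_id": sid, "parameter": parameter,
                         "condition": condition, "mean": means[j, k],
                         "sd": sds[j, k]})
    subject_table = pd.DataFrame(rows)
    group = (subject_table.groupby(["parameter", "condition"], sort=False)
             ["mean"].agg(["mean", "std"]).reset_index()
             .rename(columns={"std": "sd"}))
    return PosteriorSummary(model_id=spec.model_id,
                            subject_table=subject_table,
                            group_table=group, rhat=post.rhat())


def omega_difference(summary: PosteriorSummary, protection_label: str,
                     other_label: str, parameter: str = "omega") -> pd.Series:
    """Per-subject protection-minus-other parameter difference.

    Positive values reflect more of the parameter (by default more
    model-based control) on the protection variant.
    """
    prot = summary.subject_means(parameter, protection_label)
    other = summary.subject_means(parameter, other_label)
    return (prot - other).rename(f"{parameter}_difference")
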