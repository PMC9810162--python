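"""Model-agnostic behavioural analyses.

Stay-probability coding and its logistic mixed model dissociate the two
control systems: a main effect of the previous trial's outcome on the
probability of revisiting the same creature indicates model-based
control (outcome knowledge generalizes across first-stage states),
whereas an outcome x same-state interaction indicates model-free control
(the effect is confined to repeats of the same first-stage state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .agent import internal_reward
from .data import MISSING, SubjectDataset
from .task import PayoffWalkSet

OUTCOME_CENTER = 4.5  # midpoint of the 0-9 outcome scale


def code_stay(data: SubjectDataset) -> pd.DataFrame:
    """Derive one stay record per analyzable trial after the first.

    ``stay`` is defined on creatures (second-stage states), not dwellings,
    so a model-based repeat from the other first-stage state still counts.
    The previous outcome is the internal (valence-aligned) reward centered
    on the scale midpoint; ``same_state`` and ``high_stakes`` are +/-0.5
    effect codes.  Trials following a miss have no defined previous trial
    and are dropped, as are missed trials themselves.
    """
    if not np.all(np.diff(data.trial_index) > 0):
        raise ValueError("trials must be ordered by trial_index")
    sub = data.subset(data.analyzable)
    hi = int(sub.stakes.max()) if len(sub) else 5
    rows = []
    for i in range(1, len(sub)):
        if sub.choice[i] == MISSING or sub.choice[i - 1] == MISSING:
            continue
        prev_outcome = internal_reward(sub.variant, int(sub.outcome_units[i - 1]))
        rows.append({
            "subject_id": sub.subject_id,
            "variant": sub.variant,
            "trial_index": int(sub.trial_index[i]),
            "stay": int(sub.creature[i] == sub.creature[i - 1]),
            "prev_outcome": prev_outcome - OUTCOME_CENTER,
            "same_state": 0.5 if sub.state[i] == sub.state[i - 1] else -0.5,
            "high_stakes": 0.5 if sub.stakes[i] == hi else -0.5,
            "trial_position": int(sub.trial_index[i]),
        })
    return pd.DataFrame(rows, columns=[
        "subject_id", "variant", "trial_index", "stay", "prev_outcome",
        "same_state", "high_stakes", "trial_position"])


@dataclass
class StayModelResult:
    table: pd.DataFrame  # term, est, se, z, ci_lo, ci_hi
    tau00: float         # subject random-intercept variance
    r2_conditional: float
    n_obs: int
    n_subjects: int
    method: str
    converged: bool

    def coef(self, term: str) -> pd.Series:
        sel = self.table[self.table.term == term]
        if sel.empty:
            raise KeyError(f"no term {term!r}; have {list(self.table.term)}")
        return sel.iloc[0]

    def simple_slope(self, same_state: bool) -> tuple[float, float]:
        """Outcome slope at one level of same_state (estimate, approx SE).

        SE treats the two coefficients as independent (mean-field
        posterior does not expose their covariance).
        """
        b_out = self.coef("prev_outcome")
        b_int = self.coef("prev_outcome:same_state")
        code = 0.5 if same_state else -0.5
        est = b_out.est + code * b_int.est
        se = float(np.sqrt(b_out.se ** 2 + 0.25 * b_int.se ** 2))
        return float(est), se


_BASE_TERMS = ["prev_outcome", "same_state", "prev_outcome:same_state"]


def _design(records: pd.DataFrame, extra_terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(records))})
    for term in _BASE_TERMS + list(extra_terms):
        parts = term.split(":")
        col = records[parts[0]].to_numpy().copy()
        for p in parts[1:]:
            col = col * records[p].to_numpy()
        X[term] = col
    return X


def fit_stay_model(records: pd.DataFrame,
                   extra_terms: tuple[str, ...] = ()) -> StayModelResult:
    """Logistic mixed model of stay with a subject random intercept.

    Default fixed effects: prev_outcome * same_state; additional
    interaction terms (e.g. ``"prev_outcome:high_stakes"``) may be
    supplied.  Fit by mean-field variational Bayes, a Laplace-class
    marginal-likelihood approximation; falls back to an ordinary logistic
    regression when only one subject is present.
    """
    if records.empty:
        raise ValueError("no stay records")
    subjects = records["subject_id"].unique()
    X = _design(records, extra_terms)
    y = records["stay"].to_numpy().astype(float)

    if len(subjects) < 2:
        warnings.warn("single subject: fitting plain logistic regression",
                      RuntimeWarning, stacklevel=2)
        fit = sm.Logit(y, X).fit(disp=0)
        table = pd.DataFrame({
            "term": X.columns, "est": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(), "z": fit.tvalues.to_numpy()})
        table["ci_lo"] = table.est - 1.96 * table.se
        table["ci_hi"] = table.est + 1.96 * table.se
        var_f = float(np.var(X.to_numpy() @ fit.params.to_numpy()))
        r2 = var_f / (var_f + np.pi ** 2 / 3)
        return StayModelResult(table=table, tau00=0.0, r2_conditional=r2,
                               n_obs=len(y), n_subjects=1,
                               method="logit", converged=bool(fit.mle_retvals
                                                              ["converged"]))

    codes = pd.Categorical(records["subject_id"]).codes
    exog_vc = np.zeros((len(y), len(subjects)))
    exog_vc[np.arange(len(y)), codes] = 1.0
    ident = np.zeros(len(subjects), dtype=int)
    model = BinomialBayesMixedGLM(y, X.to_numpy(), exog_vc, ident,
                                  vcp_p=2.0, fe_p=2.0)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit_vb(verbose=False)
        except Exception as err:  # separation / optimizer failure
            raise RuntimeError(f"stay model failed to converge: {err}") from err
    est = res.fe_mean
    se = res.fe_sd
    table = pd.DataFrame({"term": X.columns, "est": est, "se": se,
                          "z": est / se})
    table["ci_lo"] = table.est - 1.96 * table.se
    table["ci_hi"] = table.est + 1.96 * table.se
    tau00 = float(np.exp(res.vcp_mean[0]) ** 2)
    var_f = float(np.var(X.to_numpy() @ est))
    r2 = (var_f + tau00) / (var_f + tau00 + np.pi ** 2 / 3)
    return StayModelResult(table=table, tau00=tau00, r2_conditional=r2,
                           n_obs=len(y), n_subjects=len(subjects),
                           method="vb_mixed", converged=converged)


def corrected_reward_rate(data: SubjectDataset, walks: PayoffWalkSet) -> float:
    """Average outcome earned divided by average outcome available.

    Both sides use the internal (valence-aligned) scale so that the ratio
    is comparable across framings; "available" averages the two
    creatures' walk values over the analyzable responded trials.
    """
    keep = data.analyzable & (data.choice != MISSING)
    if not keep.any():
        raise ValueError("no analyzable responded trials")
    earned = np.mean([internal_reward(data.variant, int(o))
                      for o in data.outcome_units[keep]])
    avail = walks.values[data.trial_index[keep]]
    if data.variant == "punishment":
        avail = 9.0 - avail
    denom = float(avail.mean())
    if denom == 0:
        raise ZeroDivisionError("no outcome available on average")
    return float(earned) / denom


def apply_exclusions(data: SubjectDataset,
                     comprehension_score: float | None = None,
                     miss_threshold: float = 0.20,
                     comprehension_threshold: float = 0.50
                     ) -> tuple[bool, str | None]:
    """Keep/drop decision with reason.

    Drop iff strictly more than 20% of analyzable trials were missed, or
    the comprehension score (when provided) is below 50%.
    """
    frac = data.missed_fraction
    if frac > miss_threshold:
        return False, f"missed {frac:.1%} of trials (> {miss_threshold:.0%})"
    if comprehension_score is not None and comprehension_score < comprehension_threshold:
        return False, (f"comprehension {comprehension_score:.0%} "
                       f"< {comprehension_threshold:.0%}")
    return True, None
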