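"""Metacognitive and predictive bias from probe ratings.

Bias is operationalized as the per-subject slope linking a probe rating
(certainty, or estimated outcome) to the outcome actually realized on
that trial: random-slope coefficients from a linear mixed model of
rating on outcome, or ordinary per-subject least squares as a fallback.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .data import MISSING, SubjectDataset
from .hbayes import PosteriorSummary

MIN_PROBES = 3  # slopes are undefined below this many probes


def extract_probes(data: SubjectDataset) -> dict[str, pd.DataFrame]:
    """Pull (outcome, rating) pairs for each probe type from one session.

    Only analyzable responded trials qualify.  Ratings outside 0-9, or a
    trial carrying both probe types, raise a validation error.
    """
    both = (data.certainty != MISSING) & (data.outcome_estimate != MISSING)
    if both.any():
        raise ValueError("certainty and outcome_estimate on the same trial")
    out = {}
    for kind, col in (("certainty", data.certainty),
                      ("estimate", data.outcome_estimate)):
        mask = data.analyzable & (col != MISSING) & (data.choice != MISSING)
        ratings = col[mask]
        if ratings.size and (ratings.min() < 0 or ratings.max() > 9):
            raise ValueError(f"{kind} rating outside [0, 9]")
        out[kind] = pd.DataFrame({
            "subject_id": data.subject_id,
            "variant": data.variant,
            "trial_index": data.trial_index[mask],
            "outcome": data.outcome_units[mask].astype(float),
            "rating": ratings.astype(float),
        })
    return out


def _per_subject_slopes(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, grp in table.groupby("subject_id", sort=True):
        if len(grp) < MIN_PROBES or grp["outcome"].nunique() < 2:
            continue
        slope = np.polyfit(grp["outcome"], grp["rating"], 1)[0]
        rows.append({"subject_id": sid, "slope": float(slope),
                     "n_probes": len(grp)})
    return pd.DataFrame(rows, columns=["subject_id", "slope", "n_probes"])


def bias_slopes(table: pd.DataFrame, method: str = "mixed") -> pd.DataFrame:
    """Per-subject rating-on-outcome slopes.

    ``mixed`` fits a linear mixed model with random intercepts and slopes
    and returns fixed + random slope per subject (shrunken); it falls
    back to ``per_subject`` OLS with a warning when it cannot converge.
    Subjects with fewer than three probes are omitted.
    """
    if method not in ("mixed", "per_subject"):
        raise ValueError("method must be 'mixed' or 'per_subject'")
    counts = table.groupby("subject_id").size()
    keep = counts[counts >= MIN_PROBES].index
    table = table[table["subject_id"].isin(keep)]
    if table.empty:
        return pd.DataFrame(columns=["subject_id", "slope", "n_probes"])
    if method == "per_subject" or table["subject_id"].nunique() < 2:
        return _per_subject_slopes(table)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("rating ~ outcome", table,
                                groups=table["subject_id"],
                                re_formula="~outcome")
            res = model.fit(reml=True)
        if not res.converged:
            raise RuntimeError("MixedLM did not converge")
    except Exception as err:
        warnings.warn(f"mixed bias model failed ({err}); "
                      "falling back to per-subject OLS",
                      RuntimeWarning, stacklevel=2)
        return _per_subject_slopes(table)
    fe_slope = float(res.fe_params["outcome"])
    rows = []
    for sid, re in res.random_effects.items():
        rows.append({"subject_id": sid,
                     "slope": fe_slope + float(re.get("outcome", 0.0)),
                     "n_probes": int(counts[sid])})
    return pd.DataFrame(rows).sort_values("subject_id", ignore_index=True)


def bias_coefficients(datasets: list[SubjectDataset],
                      method: str = "mixed") -> pd.DataFrame:
    """Metacognitive and predictive bias per subject x variant."""
    frames = []
    for variant in sorted({d.variant for d in datasets}):
        tables = {"certainty": [], "estimate": []}
        for d in datasets:
            if d.variant != variant:
                continue
            probes = extract_probes(d)
            for kind in tables:
                tables[kind].append(probes[kind])
        slopes = {}
        for kind, parts in tables.items():
            tab = pd.concat(parts, ignore_index=True)
            slopes[kind] = bias_slopes(tab, method=method).set_index(
                "subject_id")["slope"]
        merged = pd.DataFrame({
            "metacog_slope": slopes["certainty"],
            "predict_slope": slopes["estimate"],
        })
        merged.index.name = "subject_id"
        merged = merged.reset_index()
        merged.insert(1, "variant", variant)
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def relate_bias_to_params(bias: pd.DataFrame, summary: PosteriorSummary,
                          parameters: tuple[str, ...] = ("omega", "alpha")
                          ) -> pd.DataFrame:
    """Per-variant OLS of fitted parameters on the bias coefficients.

    One row per (variant, parameter, bias type).  A regression whose
    predictor or response is constant across subjects is flagged
    ``degenerate`` instead of reporting a slope.
    """
    rows = []
    for variant, grp in bias.groupby("variant", sort=True):
        for parameter in parameters:
            try:
                vals = summary.subject_means(parameter, variant)
            except KeyError:
                vals = summary.subject_means(parameter, "shared")
            for bias_col in ("metacog_slope", "predict_slope"):
                merged = grp.set_index("subject_id")[[bias_col]].join(
                    vals.rename("param"), how="inner").dropna()
                if len(merged) < 3:
                    raise ValueError(
                        f"fewer than 3 matched subjects for {variant}/"
                        f"{parameter}/{bias_col}")
                x = merged[bias_col].to_numpy()
                y = merged["param"].to_numpy()
                degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
                if degenerate:
                    est = se = t = np.nan
                else:
                    X = np.column_stack([np.ones_like(x), x])
                    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
                    dof = len(y) - 2
                    resid = y - X @ coef
                    s2 = float(resid @ resid) / dof
                    se = float(np.sqrt(
                        s2 * np.linalg.inv(X.T @ X)[1, 1]))
                    est = float(coef[1])
                    t = est / se if se > 0 else np.nan
                rows.append({
                    "variant": variant, "parameter": parameter,
                    "bias_type": bias_col, "n": len(merged), "est": est,
                    "se": se, "t": t,
                    "ci_lo": est - 1.96 * se if not degenerate else np.nan,
                    "ci_hi": est + 1.96 * se if not degenerate else np.nan,
                    "degenerate": bool(degenerate),
                })
    return pd.DataFrame(rows)
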