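"""Watanabe-Akaike information criterion from pointwise log-likelihoods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray
    model_id: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.pointwise_lppd)


def waic(pointwise: np.ndarray, model_id: str = "") -> WaicResult:
    """Compute WAIC from a [draws x observations] log-likelihood matrix.

    lppd_i = log mean_s exp(ll[s, i]) via log-sum-exp; the effective
    parameter count p_waic_i is the sample (n-1 denominator) variance of
    ll[:, i] over draws; waic = -2 (lppd - p_waic).
    """
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a [draws >= 2, observations] matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood entries")
    n_draws = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = np.var(ll, axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(waic=-2.0 * (lppd - p_waic), lppd=lppd, p_waic=p_waic,
                      pointwise_lppd=lppd_i, pointwise_p=p_i,
                      model_id=model_id)


def rank_models(results: dict[str, WaicResult],
                atol: float = 1e-9) -> pd.DataFrame:
    """Rank models by ascending WAIC; report pairwise deltas vs the best.

    ``delta_pct`` is the delta as a percentage of the best (lowest) WAIC
    magnitude.  Exact ties are flagged.
    """
    if not results:
        raise ValueError("no results to rank")
    n_obs = {m: r.n_obs for m, r in results.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"observation counts differ across models: {n_obs}")
    order = sorted(results, key=lambda m: results[m].waic)
    best = results[order[0]].waic
    rows = []
    for rank, m in enumerate(order, start=1):
        r = results[m]
        rows.append({
            "model_id": m, "rank": rank, "waic": r.waic, "lppd": r.lppd,
            "p_waic": r.p_waic, "delta_waic": r.waic - best,
            "delta_pct": 100.0 * (r.waic - best) / abs(best) if best else np.nan,
            "tied_with_best": rank > 1 and abs(r.waic - best) <= atol,
        })
    return pd.DataFrame(rows)
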