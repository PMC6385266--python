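"""AICc model selection, model averaging and relative variable importance.

Given the 40 candidate mixed models fit to one complexity response, this
module ranks them by AICc, forms the top model set (all models within
4 delta-AICc of the best), and summarises it by:

* **Akaike weights** w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2),
  computed over the full converged candidate set;
* **model-averaged coefficients** over the top set with renormalised
  weights, using full (zero-substitution) averaging: a model that
  excludes a term contributes a coefficient of 0.  Unconditional
  standard errors follow the Burnham-Anderson formula
  SE_bar = sum_i w'_i * sqrt(se_i^2 + (beta_i - beta_bar)^2);
* **relative variable importance (RVI)**: per predictor, the sum of
  (renormalised top-set) weights of the models containing it, with a
  maximum possible value of 1;
* **conditional R^2** (Nakagawa-Schielzeth): the proportion of variance
  attributed to fixed plus random effects, using the observation-
  weighted mean residual variance when the fit is heteroscedastic.

A flag switches RVI/averaging to the full candidate set, since usage in
the literature varies between "all models" and "top-set" denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import TERMS, LMMFit

__all__ = [
    "selection_table",
    "model_average",
    "rvi",
    "conditional_r2",
]

_COEF_COLUMNS = [
    "heat",
    "dist_medium",
    "dist_high",
    "branching",
    "plating",
    "massive",
    "heat:dist_medium",
    "heat:dist_high",
]


def conditional_r2(fit: LMMFit) -> float:
    """Nakagawa-Schielzeth conditional R^2 of one fit.

    R2c = (var(X beta) + s2_site) / (var(X beta) + s2_site + s2_resid_bar),
    with s2_resid_bar the observation-weighted mean of the per-period
    residual variances sigma_resid^2 * delta_g^2.
    """
    var_fixed = float(np.var(fit.fitted, ddof=1)) if fit.X.shape[1] > 1 else 0.0
    s2_site = fit.sigma_site**2
    d2 = np.where(fit.group_index == 1, fit.delta_after**2, 1.0)
    s2_resid = fit.sigma_resid**2 * float(np.mean(d2))
    return (var_fixed + s2_site) / (var_fixed + s2_site + s2_resid)


def selection_table(
    fits: list[LMMFit], delta_threshold: float = 4.0
) -> pd.DataFrame:
    """Rank converged fits by AICc.

    Returns a DataFrame sorted by AICc with one row per model: term
    presence flags, df (parameter count), log-likelihood, AICc,
    delta-AICc, Akaike weight (over the full converged set),
    conditional R^2 and a ``top_set`` flag for rows within
    ``delta_threshold`` of the best model.  Non-converged fits are
    dropped with a warning already emitted at fit time.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not usable:
        raise ValueError("no converged fits to rank")
    aiccs = np.array([f.aicc for f in usable])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    rows = []
    for f, d, wi in zip(usable, delta, w):
        row = {
            "model": f.spec.name,
            **{t: t in f.spec.terms for t in TERMS},
            "interaction": f.spec.interaction,
            "df": f.k,
            "loglik": f.loglik,
            "aicc": f.aicc,
            "delta_aicc": d,
            "weight": wi,
            "cond_r2": conditional_r2(f),
            "top_set": d <= delta_threshold,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    table["_fit"] = usable
    table = table.sort_values("aicc", kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def _top_fits(table: pd.DataFrame, top_only: bool) -> tuple[list[LMMFit], np.ndarray]:
    sub = table[table["top_set"]] if top_only else table
    fits = list(sub["_fit"])
    w = sub["weight"].to_numpy(dtype=float)
    return fits, w / w.sum()


def rvi(table: pd.DataFrame, top_only: bool = True) -> pd.Series:
    """Relative variable importance per predictor.

    The sum of Akaike weights (renormalised within the top set by
    default) across the models containing each predictor; the
    interaction is tracked as its own predictor.
    """
    fits, w = _top_fits(table, top_only)
    out = {t: 0.0 for t in TERMS}
    out["heat:disturbance"] = 0.0
    for f, wi in zip(fits, w):
        for t in f.spec.terms:
            out[t] += wi
        if f.spec.interaction:
            out["heat:disturbance"] += wi
    return pd.Series(out, name="rvi")


def model_average(table: pd.DataFrame, top_only: bool = True) -> pd.DataFrame:
    """Model-averaged coefficients, unconditional SEs and 95% CIs.

    Full (zero-substitution) averaging over the top model set with
    renormalised weights: a coefficient absent from a model enters the
    average as 0 with SE 0.  The 95% interval is the normal
    approximation beta_bar +/- 1.96 * SE_bar.
    """
    fits, w = _top_fits(table, top_only)
    rows = []
    for name in _COEF_COLUMNS:
        betas = np.zeros(len(fits))
        ses = np.zeros(len(fits))
        present = np.zeros(len(fits), dtype=bool)
        for i, f in enumerate(fits):
            if name in f.term_names:
                j = f.term_names.index(name)
                betas[i], ses[i], present[i] = f.beta[j], f.se[j], True
        if not present.any():
            continue
        beta_bar = float(np.sum(w * betas))
        se_bar = float(np.sum(w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        rows.append(
            {
                "term": name,
                "estimate": beta_bar,
                "se": se_bar,
                "ci_lo": beta_bar - 1.96 * se_bar,
                "ci_hi": beta_bar + 1.96 * se_bar,
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    importance = rvi(table, top_only=top_only)
    term_of = {
        "heat": "heat",
        "dist_medium": "disturbance",
        "dist_high": "disturbance",
        "branching": "branching",
        "plating": "plating",
        "massive": "massive",
        "heat:dist_medium": "heat:disturbance",
        "heat:dist_high": "heat:disturbance",
    }
    out["rvi"] = [importance[term_of[t]] for t in out.index]
    return out
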