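"""Linear mixed-effects models with a random site intercept and
period-specific residual variances, fit by maximum likelihood.

The model for a plot-level complexity response y is

    y = X beta + Z b + eps,
    b_site ~ N(0, sigma_site^2),
    eps_i  ~ N(0, sigma_resid^2 * delta_{g(i)}^2),

where Z maps observations to sites and g(i) is the survey-period group
('before' or 'after').  delta_before is fixed at 1; delta_after is a
free variance-ratio multiplier when the heteroscedastic ("varIdent")
structure is enabled, so residual spread may differ between periods.

Estimation is by full maximum likelihood (not REML): the model-selection
stage compares fits with different fixed-effect structures, and only ML
log-likelihoods are comparable across those.  beta is profiled out by
generalized least squares at every variance evaluation, and the variance
parameters are optimised on the log scale with a small multi-start to
reduce local-optimum risk.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

__all__ = [
    "TERMS",
    "ModelSpec",
    "LMMFit",
    "rescale_half_sd",
    "enumerate_models",
    "design_matrix",
    "fit_lmm",
    "aicc",
]

#: Candidate fixed-effect terms, in canonical order.
TERMS = ("heat", "disturbance", "branching", "plating", "massive")

PERIOD_LEVELS = ("before", "after")
DISTURBANCE_LEVELS = ("low", "medium", "high")


def rescale_half_sd(values) -> np.ndarray:
    """Standardise a continuous predictor to mean 0 and SD 0.5.

    Computed as (x - mean) / (2 * SD) with the sample SD, which puts
    continuous predictors on a scale directly comparable with binary
    ones.  Raises on constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to rescale")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance predictor cannot be rescaled")
    return (x - x.mean()) / (2.0 * sd)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure.

    ``terms`` is a subset of :data:`TERMS`; ``interaction`` adds the
    heat x disturbance two-way interaction and requires both of those
    main effects to be present.
    """

    terms: tuple[str, ...]
    interaction: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        object.__setattr__(
            self, "terms", tuple(t for t in TERMS if t in self.terms)
        )
        if self.interaction and not {"heat", "disturbance"} <= set(self.terms):
            raise ValueError("interaction requires both heat and disturbance")

    @property
    def name(self) -> str:
        parts = list(self.terms) or ["1"]
        if self.interaction:
            parts.append("heat:disturbance")
        return " + ".join(parts)


def enumerate_models() -> list[ModelSpec]:
    """All-subsets candidate set: 32 main-effect subsets plus the 8
    heat x disturbance interaction variants -- 40 models, deterministic
    lexicographic order."""
    specs: list[ModelSpec] = []
    for r in range(len(TERMS) + 1):
        for combo in itertools.combinations(TERMS, r):
            specs.append(ModelSpec(terms=combo))
            if {"heat", "disturbance"} <= set(combo):
                specs.append(ModelSpec(terms=combo, interaction=True))
    return specs


def _check_levels(series: pd.Series, levels: tuple[str, ...], what: str) -> None:
    seen = set(series.unique())
    unknown = seen - set(levels)
    if unknown:
        raise ValueError(f"unseen {what} level(s): {sorted(unknown)}")


def design_matrix(
    spec: ModelSpec, records: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix with treatment (reference) coding.

    References are 'before' for period and 'low' for disturbance, so the
    intercept is the expected response of an undisturbed plot before the
    heat stress.  Continuous density predictors are used as given (the
    pipeline rescales them beforehand).  Returns (X, column names).
    """
    if records.empty:
        raise ValueError("records table is empty")
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    _check_levels(records["period"], PERIOD_LEVELS, "period")
    _check_levels(records["disturbance"], DISTURBANCE_LEVELS, "disturbance")
    heat = (records["period"] == "after").to_numpy(dtype=float)
    dmed = (records["disturbance"] == "medium").to_numpy(dtype=float)
    dhigh = (records["disturbance"] == "high").to_numpy(dtype=float)
    if "heat" in spec.terms:
        cols.append(heat)
        names.append("heat")
    if "disturbance" in spec.terms:
        cols += [dmed, dhigh]
        names += ["dist_medium", "dist_high"]
    for term in ("branching", "plating", "massive"):
        if term in spec.terms:
            cols.append(records[term].to_numpy(dtype=float))
            names.append(term)
    if spec.interaction:
        cols += [heat * dmed, heat * dhigh]
        names += ["heat:dist_medium", "heat:dist_high"]
    return np.column_stack(cols), names


@dataclass
class LMMFit:
    """A fitted mixed model: estimates, variance components, AICc."""

    spec: ModelSpec
    beta: np.ndarray
    se: np.ndarray
    term_names: list[str]
    sigma_site: float
    sigma_resid: float
    delta_after: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    varident: bool
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    site_index: np.ndarray = field(repr=False)
    group_index: np.ndarray = field(repr=False)  # 0 = before, 1 = after

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.beta

    def coef(self) -> dict[str, float]:
        return dict(zip(self.term_names, self.beta))


def wald_ci(fit: "LMMFit", level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient t-intervals with containment degrees of freedom.

    Each fixed effect is assigned the grouping level at which it varies,
    in the style of nlme: covariates constant within a site (intercept,
    disturbance contrasts) use between-site df = n_sites - q_between,
    covariates varying within a site (heat, densities, interactions)
    use within df = n - n_sites - q_within.  This matters at the scale
    of this design (a handful of sites), where a normal quantile is
    anticonservative for site-level contrasts.
    """
    from scipy.stats import t as t_dist

    n_sites = int(fit.site_index.max()) + 1
    site_level = []
    for j, nm in enumerate(fit.term_names):
        col = fit.X[:, j]
        varies_within = any(
            np.ptp(col[fit.site_index == s]) > 0 for s in range(n_sites)
        )
        site_level.append(not varies_within)
    q_between = sum(site_level)
    q_within = len(site_level) - q_between
    df_between = max(n_sites - q_between, 1)
    df_within = max(fit.n - n_sites - q_within, 1)
    rows = []
    for j, nm in enumerate(fit.term_names):
        df = df_between if site_level[j] else df_within
        tq = t_dist.ppf(0.5 + level / 2, df)
        rows.append(
            {
                "term": nm,
                "estimate": fit.beta[j],
                "se": fit.se[j],
                "df": df,
                "ci_lo": fit.beta[j] - tq * fit.se[j],
                "ci_hi": fit.beta[j] + tq * fit.se[j],
            }
        )
    return pd.DataFrame(rows).set_index("term")


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _neg_loglik(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    ZZt: np.ndarray,
    group: np.ndarray,
    varident: bool,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile negative log-likelihood at variance-shape parameters.

    theta = log(sigma_site / sigma_resid) [, log(delta_after)]: both
    beta and the overall residual scale sigma_resid^2 are profiled out
    analytically, so the numeric optimisation is 1-2 dimensional.
    Returns (nll, beta_hat, cov_beta, sigma_resid^2).
    """
    n, p = X.shape
    bad = (np.inf, np.full(p, np.nan), np.full((p, p), np.nan), np.nan)
    if np.any(np.abs(theta) > 30):
        return bad
    lam = np.exp(2 * theta[0])                       # sigma_site^2 / sigma_resid^2
    delta = np.exp(theta[1]) if varident else 1.0
    d = np.where(group == 1, delta**2, 1.0)
    W = lam * ZZt + np.diag(d)                       # V = sigma_resid^2 * W
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        return bad
    logdet_w = 2.0 * np.sum(np.log(np.diag(L)))
    Xs = solve_triangular(L, X, lower=True)
    ys = solve_triangular(L, y, lower=True)
    try:
        cov_unscaled = np.linalg.inv(Xs.T @ Xs)
    except np.linalg.LinAlgError:
        return bad
    beta = cov_unscaled @ (Xs.T @ ys)
    r = ys - Xs @ beta
    rss = float(r @ r)
    if rss <= 0:
        return bad
    s2 = rss / n                                     # profiled ML estimate
    nll = 0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet_w + n)
    # SEs use the df-corrected scale: the plug-in ML scale is biased low
    # by (n - p)/n, which is material at p ~ 10 on ~50 observations
    s2_se = rss / max(n - p, 1)
    return float(nll), beta, s2_se * cov_unscaled, s2


def fit_lmm(
    spec: ModelSpec,
    records: pd.DataFrame,
    response: str = "response",
    varident: bool = False,
    n_starts: int = 3,
) -> LMMFit:
    """Fit one candidate mixed model by maximum likelihood.

    ``records`` must carry columns site, period, disturbance and the
    (already rescaled) growth-form densities, plus the response column.
    With ``varident=True`` the after-period residual SD is scaled by a
    free parameter ``delta_after``.
    """
    X, names = design_matrix(spec, records)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    y = records[response].to_numpy(dtype=float)
    sites = pd.Categorical(records["site"]).codes.astype(int)
    if len(np.unique(sites)) < 2:
        raise ValueError("need at least 2 sites for a site random effect")
    group = (records["period"] == "after").to_numpy(dtype=int)
    ZZt = (sites[:, None] == sites[None, :]).astype(float)

    # moment-based starting values from an OLS fit
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    site_means = np.bincount(sites, weights=resid) / np.bincount(sites)
    s_site0 = max(float(np.std(site_means, ddof=0)), 1e-3)
    s_resid0 = max(float(np.std(resid - site_means[sites], ddof=0)), 1e-3)
    sd_b = np.std(resid[group == 0]) if np.any(group == 0) else s_resid0
    sd_a = np.std(resid[group == 1]) if np.any(group == 1) else s_resid0
    delta0 = max(sd_a, 1e-3) / max(sd_b, 1e-3)
    base = [np.log(s_site0 / s_resid0)]
    if varident:
        base.append(np.log(delta0))
    base = np.array(base)

    rng = np.random.default_rng(0)  # fixed jitter stream: fits are deterministic
    starts = [base] + [base + rng.normal(0, 0.5, size=base.size) for _ in range(n_starts - 1)]

    best = None
    for x0 in starts:
        res = minimize(
            lambda th: _neg_loglik(th, X, y, ZZt, group, varident)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    nll, beta, cov, s2 = _neg_loglik(best.x, X, y, ZZt, group, varident)
    converged = bool(best.success and np.isfinite(nll))
    if not converged:
        warnings.warn(f"LMM fit did not converge for model '{spec.name}'", stacklevel=2)
    se = np.sqrt(np.diag(cov))
    k = p + 2 + (1 if varident else 0)
    ll = -nll
    sigma_resid = float(np.sqrt(s2))
    return LMMFit(
        spec=spec,
        beta=beta,
        se=se,
        term_names=names,
        sigma_site=float(np.exp(best.x[0]) * sigma_resid),
        sigma_resid=sigma_resid,
        delta_after=float(np.exp(best.x[1])) if varident else 1.0,
        loglik=float(ll),
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=converged,
        varident=varident,
        X=X,
        y=y,
        site_index=sites,
        group_index=group,
    )
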