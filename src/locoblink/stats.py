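"""Statistical machinery shared by the eyeblink and split-belt analyses.

Trial-level analyses use linear mixed models with random slopes and
intercepts per mouse, with fixed effects tested by F tests using the
Satterthwaite denominator-degrees-of-freedom approximation.  Animal-level
regressions (e.g. learning onset against locomotor activity) use
outlier-resistant bisquare iteratively-reweighted least squares.

statsmodels' MixedLM provides the (RE)ML estimates; the Satterthwaite
approximation is computed here from the REML log-likelihood surface because
no installed package exposes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


# --------------------------------------------------------------------------
# REML log-likelihood and Satterthwaite degrees of freedom
# --------------------------------------------------------------------------

def _split_groups(values: np.ndarray, groups: np.ndarray) -> list[np.ndarray]:
    order = {}
    for g in groups:
        if g not in order:
            order[g] = len(order)
    idx = [np.flatnonzero(groups == g) for g in order]
    return [values[i] for i in idx]


def _unpack_theta(theta, q):
    tri = np.zeros((q, q))
    tri[np.tril_indices(q)] = theta[:-1]
    G = tri + tri.T - np.diag(np.diag(tri))
    return G, theta[-1]


def _group_crossprods(y_list, x_list, z_list):
    """Per-group sufficient statistics for the marginal likelihood.

    With V_i = s I + Z_i G Z_i', the Woodbury identity reduces every term
    of the restricted likelihood to the cross-products
    (X'X, X'Z, Z'Z, X'y, Z'y, y'y, n) per group, so evaluating the
    likelihood at new variance parameters costs O(q^3) per group instead
    of O(n^3).
    """
    stats = []
    for y, X, Z in zip(y_list, x_list, z_list):
        stats.append({
            "xx": X.T @ X, "xz": X.T @ Z, "zz": Z.T @ Z,
            "xy": X.T @ y, "zy": Z.T @ y, "yy": float(y @ y),
            "n": len(y),
        })
    return stats


def _whitened_crossprods(st, G, s):
    """X'V^-1X, X'V^-1y, y'V^-1y and log|V| for one group via Woodbury."""
    q = G.shape[0]
    K = np.eye(q) + st["zz"] @ G / s
    sign, ldK = np.linalg.slogdet(K)
    if sign <= 0 or s <= 0:
        return None
    M = G @ np.linalg.inv(K)  # symmetric: Z M Z' is the Woodbury correction
    xz, zy = st["xz"], st["zy"]
    xtvx = st["xx"] / s - xz @ M @ xz.T / s**2
    xtvy = st["xy"] / s - xz @ M @ zy / s**2
    ytvy = st["yy"] / s - zy @ M @ zy / s**2
    logdet = st["n"] * np.log(s) + ldK
    return xtvx, xtvy, ytvy, logdet


def _reml_loglik(theta, stats, q, p):
    """Restricted log-likelihood at variance parameters theta.

    theta packs the lower triangle of the random-effects covariance G
    (row-major) followed by the residual variance s.  Constant terms in
    the likelihood are dropped; only derivatives matter here.
    """
    G, s = _unpack_theta(theta, q)
    if s <= 0:
        return -np.inf
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for st in stats:
        out = _whitened_crossprods(st, G, s)
        if out is None:
            return -np.inf
        xtvx += out[0]
        xtvy += out[1]
        ytvy += out[2]
        logdet_v += out[3]
    sign, ld_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    return -0.5 * (logdet_v + ld_x + quad)


def _fixed_effects_cov(theta, stats, q, p):
    G, s = _unpack_theta(theta, q)
    xtvx = np.zeros((p, p))
    for st in stats:
        out = _whitened_crossprods(st, G, s)
        if out is None:
            return np.full((p, p), np.nan)
        xtvx += out[0]
    return np.linalg.inv(xtvx)


def satterthwaite_df(y, X, Z, groups, cov_re, scale, contrast) -> float:
    """Satterthwaite denominator df for a fixed-effect contrast L'beta.

    Follows the standard approximation: with f(theta) = L' Cov(beta_hat) L,
    ddf = 2 f^2 / (g' A g), where g is the gradient of f over the variance
    parameters and A their asymptotic covariance (inverse negative Hessian
    of the restricted log-likelihood).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    groups = np.asarray(groups)
    L = np.asarray(contrast, float)
    q = Z.shape[1]
    p = X.shape[1]
    y_list = _split_groups(y, groups)
    x_list = _split_groups(X, groups)
    z_list = _split_groups(Z, groups)
    stats = _group_crossprods(y_list, x_list, z_list)

    cov_re = np.atleast_2d(np.asarray(cov_re, float))
    theta = np.concatenate([cov_re[np.tril_indices(q)], [float(scale)]])

    def f(t):
        return float(L @ _fixed_effects_cov(t, stats, q, p) @ L)

    def ll(t):
        return _reml_loglik(t, stats, q, p)

    k = len(theta)
    h = 1e-4 * (np.abs(theta) + 1e-4)
    grad = np.zeros(k)
    H = np.zeros((k, k))
    with np.errstate(all="ignore"):  # degenerate surfaces handled via fallback
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            grad[i] = (f(theta + e) - f(theta - e)) / (2 * h[i])
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])

    n_fallback = max(float(len(y_list) - X.shape[1]), 1.0)
    if not np.all(np.isfinite(H)):
        return n_fallback
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return n_fallback
    denom = float(grad @ A @ grad)
    fval = f(theta)
    if denom <= 0 or not np.isfinite(denom) or fval <= 0:
        return n_fallback
    ddf = 2.0 * fval * fval / denom
    # guard against pathological surfaces: df cannot exceed residual count
    return float(np.clip(ddf, 1.0, len(y) - X.shape[1]))


# --------------------------------------------------------------------------
# Random slopes/intercepts model for trial-level data
# --------------------------------------------------------------------------

@dataclass
class MixedSlopeResult:
    """Fixed-effect slope of a per-trial predictor with Satterthwaite F test."""

    slope: float
    intercept: float
    se: float
    fstat: float
    ddf: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_groups: int
    method: str  # "mixed" or "ols"


def fit_random_slopes(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    group: str,
    alpha: float = 0.05,
) -> MixedSlopeResult:
    """Fit ``response ~ predictor`` with per-group random slopes and intercepts.

    With a single group the mixed model is unidentifiable and the fit falls
    back to ordinary least squares (with a warning).
    """
    df = data[[response, predictor, group]].dropna()
    if df[predictor].nunique() < 2:
        raise ValueError("predictor is constant; slope is unidentifiable")
    n_groups = df[group].nunique()
    y = df[response].to_numpy(float)
    x = df[predictor].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])

    if n_groups < 2:
        warnings.warn(
            "single group: falling back to ordinary least squares",
            UserWarning,
            stacklevel=2,
        )
        res = sm.OLS(y, X).fit()
        t = res.tvalues[1]
        df_resid = res.df_resid
        ci = res.conf_int(alpha)
        return MixedSlopeResult(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            se=float(res.bse[1]),
            fstat=float(t * t),
            ddf=float(df_resid),
            pvalue=float(res.pvalues[1]),
            ci_low=float(ci[1, 0]),
            ci_high=float(ci[1, 1]),
            n_groups=n_groups,
            method="ols",
        )

    groups = df[group].to_numpy()
    model = sm.MixedLM(y, X, groups=groups, exog_re=X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not np.all(np.isfinite(fit.bse_fe)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, ValueError):
            fit = model.fit(reml=True, method="powell", maxiter=500)

    slope = float(fit.fe_params[1])
    intercept = float(fit.fe_params[0])
    L = np.array([0.0, 1.0])
    cov_re = np.asarray(fit.cov_re)
    ddf = satterthwaite_df(y, X, X, groups, cov_re, float(fit.scale), L)
    se = float(np.sqrt(L @ fit.cov_params()[:2, :2] @ L))
    fstat = (slope / se) ** 2
    pvalue = float(sps.f.sf(fstat, 1, ddf))
    tcrit = sps.t.ppf(1 - alpha / 2, ddf)
    return MixedSlopeResult(
        slope=slope,
        intercept=intercept,
        se=se,
        fstat=float(fstat),
        ddf=float(ddf),
        pvalue=pvalue,
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        n_groups=n_groups,
        method="mixed",
    )


# --------------------------------------------------------------------------
# Robust (bisquare IRLS) line fit
# --------------------------------------------------------------------------

@dataclass
class RobustLineResult:
    slope: float
    intercept: float
    se: float
    tstat: float
    pvalue: float
    n_iter: int


def robust_line(
    x,
    y,
    c: float = 4.685,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RobustLineResult:
    """Outlier-resistant straight-line fit by bisquare-weighted IRLS.

    Residual scale is re-estimated each iteration from the median absolute
    deviation.  With clean data the result coincides with ordinary least
    squares; gross outliers receive zero weight once beyond ``c`` rescaled
    MADs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("robust line fit requires at least 3 points")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = np.ones_like(y)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r = y - X @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale < 1e-12:
            break
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() < 2 or np.sum(w * x**2) == 0:
            break
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    r = y - X @ beta
    dof = max(x.size - 2, 1)
    s2 = np.sum(w * r**2) / max(w.sum() - 2, 1)
    sxx = np.sum(w * (x - np.average(x, weights=np.maximum(w, 1e-12))) ** 2)
    se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.inf
    tstat = beta[1] / se if se > 0 and np.isfinite(se) else 0.0
    pvalue = float(2 * sps.t.sf(abs(tstat), dof))
    return RobustLineResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se=se,
        tstat=float(tstat),
        pvalue=pvalue,
        n_iter=n_iter,
    )


# --------------------------------------------------------------------------
# Tukey adjustment
# --------------------------------------------------------------------------

def tukey_pvalue(tstat: float, n_means: int, df: float) -> float:
    """Tukey-corrected p-value for a pairwise contrast among ``n_means`` means."""
    q = abs(tstat) * np.sqrt(2.0)
    return float(sps.studentized_range.sf(q, n_means, max(df, 2.0)))
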