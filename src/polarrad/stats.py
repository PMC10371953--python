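"""Logistic-regression helpers.

Maximum-likelihood fits go through statsmodels; when a single-predictor fit
hits perfect separation (or fails to converge) we fall back to a
Firth-style bias-reduced fit — Newton iterations on the Jeffreys-penalized
likelihood, whose score for observation i is adjusted by h_i (1/2 - p_i)
with h_i the hat-matrix diagonal. The fallback always yields finite
coefficients and a usable Wald p-value, and the caller is told via a flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth bias-reduced logistic regression.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary outcome.

    Returns
    -------
    beta, se : coefficient vector and Wald standard errors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se


def logistic_wald(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Fit y ~ 1 + z(x); return (coefficient, Wald p-value, flag).

    The predictor is standardized before fitting. Flags: "" (clean ML fit),
    "constant" (degenerate predictor), "separation" (Firth fallback).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return 0.0, 1.0, "constant"
    z = (x - x.mean()) / sd
    X = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            separated = (not res.mle_retvals.get("converged", False)) or (
                not np.all(np.isfinite(res.bse))
            ) or float(np.abs(res.params[1])) > 50
            if not separated:
                return float(res.params[1]), float(res.pvalues[1]), ""
        except Exception:
            pass
    beta, se = firth_logistic(X, y)
    if se[1] > 0:
        zstat = beta[1] / se[1]
        pval = 2 * stats.norm.sf(abs(zstat))
    else:
        pval = 1.0
    return float(beta[1]), float(pval), "separation"
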