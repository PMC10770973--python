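"""Little's MCAR test and EM estimation for incomplete multivariate normal data.

The test groups rows by missingness pattern and compares each pattern's
observed-variable means against the maximum-likelihood estimates obtained by
expectation-maximization under a single multivariate normal model:

    d^2 = sum_j m_j (ybar_j - mu_[j])' Sigma_[j]^{-1} (ybar_j - mu_[j])

where ``[j]`` restricts the EM mean/covariance to the variables observed in
pattern j and m_j is the pattern's row count. Under the MCAR null, d^2 is
asymptotically chi-squared with df = (sum_j p_j) - p degrees of freedom,
p_j being the number of observed variables in pattern j.

Categorical inputs must be numerically encoded beforehand (see
:func:`scimiss._util.encode_numeric`: binaries -> {0,1}, AIS grade -> 1-4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, SinglePatternError

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


@dataclass
class EMEstimate:
    """ML mean/covariance of an incomplete multivariate normal sample."""

    mean: np.ndarray
    covariance: np.ndarray
    n_iter: int
    converged: bool
    loglik: list  # observed-data log-likelihood per iteration


@dataclass
class LittleTestResult:
    statistic: float
    df: int
    n_patterns: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "n_patterns": int(self.n_patterns),
            "p_value": float(self.p_value),
        }


def _as_array(data) -> tuple[np.ndarray, list]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, list(range(arr.shape[1]))


def _available_case_start(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Available-case means and pairwise covariance projected to PSD."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=0)
        p = x.shape[1]
        cov = np.empty((p, p))
        for i in range(p):
            for j in range(i, p):
                both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
                if both.sum() >= 2:
                    xi = x[both, i] - x[both, i].mean()
                    xj = x[both, j] - x[both, j].mean()
                    cov[i, j] = cov[j, i] = (xi * xj).mean()
                else:
                    cov[i, j] = cov[j, i] = 0.0
    # project to positive semidefinite, keep variances strictly positive
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    w = np.clip(w, _RIDGE, None)
    return mean, (v * w) @ v.T


def _patterns(x: np.ndarray):
    """Group row indices by missingness pattern (observed-variable sets)."""
    obs = ~np.isnan(x)
    _, inverse = np.unique(obs, axis=0, return_inverse=True)
    out = []
    for code in np.unique(inverse):
        rows = np.flatnonzero(inverse == code)
        out.append((rows, np.flatnonzero(obs[rows[0]])))
    return out


def _solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a @ x = b, ridge-regularizing a singular block with a log note."""
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        eps = _RIDGE * max(1.0, float(np.trace(a)) / max(1, a.shape[0]))
        logger.warning("singular observed-block covariance; adding ridge %g", eps)
        return np.linalg.solve(a + eps * np.eye(a.shape[0]), b)


def em_norm(data, tol: float = 1e-6, max_iter: int = 500) -> EMEstimate:
    """ML mean/covariance under multivariate normality via EM.

    Rows with every variable missing are dropped with a warning; a variable
    with no observed value at all raises :class:`EstimationError`. The
    observed-data log-likelihood is non-decreasing across iterations, and
    convergence is declared when the max-abs change of all parameters falls
    below ``tol``.
    """
    x, _ = _as_array(data)
    all_missing = np.isnan(x).all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} rows with all variables missing")
        x = x[~all_missing]
    n, p = x.shape
    if n == 0 or p < 1:
        raise EstimationError("no usable rows/variables")
    if np.isnan(x).all(axis=0).any():
        bad = [int(i) for i in np.flatnonzero(np.isnan(x).all(axis=0))]
        raise EstimationError(f"variables entirely missing: {bad}")

    mean, cov = _available_case_start(x)
    patterns = _patterns(x)
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sx = np.zeros(p)
        sxx = np.zeros((p, p))
        ll = 0.0
        for rows, obs in patterns:
            xo = x[np.ix_(rows, obs)]
            m = len(rows)
            mis = np.setdiff1d(np.arange(p), obs)
            s_oo = cov[np.ix_(obs, obs)]
            dev = xo - mean[obs]
            sol = _solve(s_oo, dev.T)  # (|obs|, m)
            sign, logdet = np.linalg.slogdet(s_oo)
            if sign <= 0:  # fall back after ridge
                logdet = np.log(np.linalg.det(s_oo + _RIDGE * np.eye(len(obs))))
            ll += -0.5 * (
                m * (len(obs) * np.log(2 * np.pi) + logdet) + float(np.einsum("im,mi->", dev, sol))
            )
            if mis.size:
                s_mo = cov[np.ix_(mis, obs)]
                xm_hat = mean[mis] + (s_mo @ sol).T  # (m, |mis|)
                c_mm = cov[np.ix_(mis, mis)] - s_mo @ _solve(s_oo, s_mo.T)
                full = np.zeros((m, p))
                full[:, obs] = xo
                full[:, mis] = xm_hat
                sx += full.sum(axis=0)
                sxx += full.T @ full
                sxx[np.ix_(mis, mis)] += m * c_mm
            else:
                sx += xo.sum(axis=0)
                sxx += xo.T @ xo
        logliks.append(ll)
        new_mean = sx / n
        new_cov = sxx / n - np.outer(new_mean, new_mean)
        new_cov = (new_cov + new_cov.T) / 2
        delta = max(
            float(np.max(np.abs(new_mean - mean))), float(np.max(np.abs(new_cov - cov)))
        )
        mean, cov = new_mean, new_cov
        if delta < tol:
            converged = True
            break
    return EMEstimate(mean=mean, covariance=cov, n_iter=it, converged=converged, loglik=logliks)


def little_mcar_test(data, tol: float = 1e-6, max_iter: int = 500) -> LittleTestResult:
    """Little's chi-squared test of the MCAR null hypothesis.

    Requires at least two distinct missingness patterns (otherwise the test
    has zero degrees of freedom and :class:`SinglePatternError` is raised).
    """
    x, _ = _as_array(data)
    all_missing = np.isnan(x).all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} rows with all variables missing")
        x = x[~all_missing]
    patterns = _patterns(x)
    if len(patterns) < 2:
        raise SinglePatternError("only one missingness pattern; Little's test undefined (df = 0)")

    est = em_norm(x, tol=tol, max_iter=max_iter)
    p = x.shape[1]
    d2 = 0.0
    sum_obs = 0
    for rows, obs in patterns:
        m = len(rows)
        sum_obs += len(obs)
        ybar = np.nanmean(x[np.ix_(rows, obs)], axis=0)
        dev = ybar - est.mean[obs]
        s_oo = est.covariance[np.ix_(obs, obs)]
        d2 += m * float(dev @ _solve(s_oo, dev))
    df = sum_obs - p
    p_value = float(stats.chi2.sf(d2, df)) if df > 0 else float("nan")
    return LittleTestResult(statistic=float(d2), df=int(df), n_patterns=len(patterns), p_value=p_value)
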