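"""EM estimation and Little's MCAR test against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scimiss import em_norm, little_mcar_test
from scimiss.errors import EstimationError, SinglePatternError


def factored_ml_bivariate(x1, x2):
    """Closed-form ML estimate for a monotone bivariate pattern.

    x1 fully observed, x2 observed only where not NaN. Factorizes the
    likelihood into the marginal of x1 and the regression of x2 on x1 over
    the complete pairs (ML variances divide by n, not n-1).
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    obs = ~np.isnan(x2)
    mu1 = x1.mean()
    s11 = x1.var()
    x1c, x2c = x1[obs], x2[obs]
    s11c = x1c.var()
    s12c = ((x1c - x1c.mean()) * (x2c - x2c.mean())).mean()
    s22c = x2c.var()
    beta = s12c / s11c
    resid_var = s22c - s12c**2 / s11c
    mu2 = x2c.mean() + beta * (mu1 - x1c.mean())
    s12 = beta * s11
    s22 = resid_var + beta**2 * s11
    return np.array([mu1, mu2]), np.array([[s11, s12], [s12, s22]])


def little_d2_oracle(x, mean, cov):
    """Direct evaluation of the pattern-wise d^2 formula."""
    obs = ~np.isnan(x)
    d2 = 0.0
    sum_obs = 0
    for pat in np.unique(obs, axis=0):
        rows = (obs == pat).all(axis=1)
        cols = np.flatnonzero(pat)
        sum_obs += len(cols)
        ybar = np.nanmean(x[np.ix_(rows, cols)], axis=0)
        dev = ybar - mean[cols]
        d2 += rows.sum() * float(dev @ np.linalg.solve(cov[np.ix_(cols, cols)], dev))
    return d2, sum_obs - x.shape[1]


def test_em_complete_data_matches_closed_form():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(200, 3))
    est = em_norm(x)
    assert est.converged
    np.testing.assert_allclose(est.mean, x.mean(axis=0), atol=1e-8)
    np.testing.assert_allclose(est.covariance, np.cov(x, rowvar=False, ddof=0), atol=1e-8)


def test_em_monotone_pattern_equals_factored_likelihood():
    rng = np.random.default_rng(2)
    n = 300
    x1 = rng.normal(5, 2, size=n)
    x2 = 1.0 + 0.7 * x1 + rng.normal(0, 1, size=n)
    x2[n // 2 :] = np.nan
    est = em_norm(np.column_stack([x1, x2]), tol=1e-10)
    mean_o, cov_o = factored_ml_bivariate(x1, x2)
    np.testing.assert_allclose(est.mean, mean_o, atol=1e-6)
    np.testing.assert_allclose(est.covariance, cov_o, atol=1e-6)


def test_em_recovers_known_correlation():
    """Half the rows missing one variable; rho = 0.8 recovered within 0.05."""
    rng = np.random.default_rng(3)
    n = 10_000
    cov = np.array([[1.0, 0.8], [0.8, 1.0]])
    x = rng.multivariate_normal([0, 0], cov, size=n)
    x[rng.random(n) < 0.5, 1] = np.nan
    est = em_norm(x)
    rho = est.covariance[0, 1] / np.sqrt(est.covariance[0, 0] * est.covariance[1, 1])
    assert rho == pytest.approx(0.8, abs=0.05)


def test_em_loglik_monotone_nondecreasing():
    rng = np.random.default_rng(4)
    x = rng.multivariate_normal([0, 1, 2], np.eye(3) + 0.5, size=200)
    x[rng.random(200) < 0.3, 0] = np.nan
    x[rng.random(200) < 0.2, 2] = np.nan
    est = em_norm(x, tol=1e-10, max_iter=200)
    ll = np.array(est.loglik)
    assert np.all(np.diff(ll) >= -1e-7)


def test_em_symmetry_and_psd():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(150, 4))
    x[rng.random(150) < 0.25, 2] = np.nan
    est = em_norm(x)
    assert np.allclose(est.covariance, est.covariance.T, atol=1e-8)
    assert np.all(np.diag(est.covariance) >= 0)


def test_em_errors_on_entirely_missing_variable():
    x = np.ones((10, 2))
    x[:, 1] = np.nan
    with pytest.raises(EstimationError, match="entirely missing"):
        em_norm(x)


def test_little_statistic_matches_hand_calculation():
    """Fixed 6-row table: d^2 evaluated via the closed-form oracle."""
    x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    x2 = np.array([2.2, 2.8, 4.1, 4.9, np.nan, np.nan])
    x = np.column_stack([x1, x2])
    mean_o, cov_o = factored_ml_bivariate(x1, x2)
    d2_o, df_o = little_d2_oracle(x, mean_o, cov_o)
    res = little_mcar_test(x, tol=1e-12)
    assert res.statistic == pytest.approx(d2_o, rel=1e-5)
    assert res.df == df_o == 1
    assert res.n_patterns == 2
    assert res.p_value == pytest.approx(stats.chi2.sf(d2_o, 1), rel=1e-5)


def test_little_zero_statistic_when_pattern_means_match():
    """Pattern means equal to the EM restriction give d^2 = 0, p = 1."""
    x1 = np.array([1.0, 2.0, 3.0, 0.0, 4.0])
    x2 = np.array([4.0, 7.0, 7.0, np.nan, np.nan])
    res = little_mcar_test(np.column_stack([x1, x2]), tol=1e-12)
    assert res.statistic == pytest.approx(0.0, abs=1e-8)
    assert res.p_value == pytest.approx(1.0)


def test_little_single_pattern_rejected():
    with pytest.raises(SinglePatternError):
        little_mcar_test(np.random.default_rng(0).normal(size=(20, 2)))


def test_little_affine_invariance():
    rng = np.random.default_rng(6)
    x = rng.multivariate_normal([0, 0, 0], np.eye(3) + 0.4, size=400)
    x[rng.choice(400, 120, replace=False), 1] = np.nan
    base = little_mcar_test(x, tol=1e-10).statistic
    y = x.copy()
    y[:, 0] = 100.0 * y[:, 0] - 7.0
    y[:, 2] = -3.0 * y[:, 2] + 2.0
    scaled = little_mcar_test(y, tol=1e-10).statistic
    assert scaled == pytest.approx(base, rel=1e-5)


def test_little_accepts_dataframe(subset):
    from scimiss import MissingnessSpec, ampute, verify_mechanism

    amp = ampute(subset, MissingnessSpec("lems_w0", "MCAR"), seed=1)
    res = verify_mechanism(amp, ["lems_w52", "lems_w0", "age", "sex", "nli", "ais_grade"])
    assert res.df == 5
    assert 0 <= res.p_value <= 1


def test_null_pvalues_uniform_under_mcar():
    """p-values under the MCAR null are uniform (KS distance < 0.05)."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(2000):
        n, p = 200, 3
        a = rng.normal(size=(p, p))
        cov = a @ a.T + np.eye(p)
        x = rng.multivariate_normal(np.zeros(p), cov, size=n)
        x[rng.choice(n, 60, replace=False), 0] = np.nan
        pvals.append(little_mcar_test(x).p_value)
    dist = stats.kstest(np.asarray(pvals), "uniform").statistic
    assert dist < 0.05
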