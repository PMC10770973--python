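"""Missing-data handling strategies benchmarked by the pipeline.

Strategies
----------
cca
    complete case analysis: drop any row with a missing model variable.
mean
    unconditional mean of the observed target values.
locf
    last observation carried forward from an earlier assessment week; rows
    whose donor value is itself missing cannot be imputed and are excluded.
single_{lr,knn,svm_linear,svm_rbf,rf}
    fit one model of the target on the other variables (5-fold CV grid
    search for hyperparameters) and predict the missing entries.
multi_{pmm,norm_predict,rf}
    multiple imputation, m=25 draws, pooled by the per-entry mean:
    pmm draws regression parameters from their approximate posterior and
    copies the observed value of one of the d=5 closest predicted-mean
    donors (type-1 matching); norm_predict is the deterministic regression
    prediction (all draws coincide; logged as degenerate); rf fits a small
    forest per draw on a bootstrap of the observed rows and copies a random
    donor from a random tree's terminal node.

When the target is the baseline (explanatory) variable, the chronic outcome
is excluded from the predictors: it would not be available at baseline.
Predicted LEMS values are clipped to [0, 50] but left continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .amputation import AmputedSubset
from .errors import ConfigurationError, DonorPoolError, InsufficientDataError

logger = logging.getLogger(__name__)

METHODS = (
    "cca",
    "mean",
    "locf",
    "single_lr",
    "single_knn",
    "single_svm_linear",
    "single_svm_rbf",
    "single_rf",
    "multi_pmm",
    "multi_norm_predict",
    "multi_rf",
)

SINGLE_KINDS = ("lr", "knn", "svm_linear", "svm_rbf", "rf")
MULTI_KINDS = ("pmm", "norm_predict", "rf")

#: Default hyperparameter grids for the CV-tuned single imputers.
DEFAULT_GRIDS = {
    "lr": {},
    "knn": {"model__n_neighbors": [1, 3, 5, 10, 20]},
    "svm_linear": {"model__C": [0.1, 1.0, 10.0, 100.0]},
    "svm_rbf": {"model__C": [0.1, 1.0, 10.0, 100.0], "model__gamma": [0.001, 0.01, 0.1, 1.0]},
    "rf": {
        "model__n_estimators": [100, 500],
        "model__max_features": ["sqrt", 1.0],
        "model__min_samples_leaf": [1, 5],
    },
}

#: Reduced grid for desk-scale runs (single CPU, hundreds of subsets).
DESK_GRIDS = {
    **DEFAULT_GRIDS,
    "rf": {
        "model__n_estimators": [100],
        "model__max_features": ["sqrt"],
        "model__min_samples_leaf": [1, 5],
    },
}

_WEEK_ORDER = {"lems_w0": 0, "lems_w16": 16, "lems_w26": 26, "lems_w52": 52}
_MODEL_VARS = ["lems_w0", "lems_w52", "ais_grade", "nli", "age", "sex"]


@dataclass(frozen=True)
class ImputationModelSpec:
    """Target variable and predictor set for model-based imputation."""

    target: str
    predictors: tuple
    outcome_excluded: bool

    def __post_init__(self):
        if self.target in ("lems_w26", "lems_w52"):
            return
        # baseline target: chronic outcomes must not leak into predictors
        if any(p in ("lems_w26", "lems_w52") for p in self.predictors):
            raise ConfigurationError(
                "the chronic outcome cannot predict a baseline target variable"
            )


def default_model_spec(target: str, outcome: str = "lems_w52") -> ImputationModelSpec:
    """Predictor sets mirroring the analysis design.

    The outcome is imputed from all other model variables; the baseline
    explanatory variable only from the baseline covariates.
    """
    if target == "lems_w0":
        return ImputationModelSpec(
            target=target, predictors=("ais_grade", "nli", "age", "sex"), outcome_excluded=True
        )
    return ImputationModelSpec(
        target=target,
        predictors=("lems_w0", "ais_grade", "nli", "age", "sex"),
        outcome_excluded=False,
    )


@dataclass
class ImputationResult:
    method: str
    completed_table: pd.DataFrame | None
    pooled: pd.Series  # one value per amputed entry (empty for cca)
    draws: pd.DataFrame | None = None  # rows x m, multiple imputation only
    excluded_rows: list = field(default_factory=list)
    tuning: dict = field(default_factory=dict)


def _design(table: pd.DataFrame, predictors) -> pd.DataFrame:
    """Numeric design matrix with the documented dummy coding.

    Reference levels: AIS A, cervical, female; numeric columns pass through.
    """
    cols = {}
    for p in predictors:
        if p == "ais_grade":
            for g in ("B", "C", "D"):
                cols[f"ais_{g}"] = (table["ais_grade"] == g).astype(float)
        elif p == "nli":
            cols["nli_thoracic"] = (table["nli"] == "thoracic").astype(float)
        elif p == "sex":
            cols["sex_male"] = (table["sex"] == "male").astype(float)
        else:
            cols[p] = pd.to_numeric(table[p], errors="coerce").astype(float)
    return pd.DataFrame(cols, index=table.index)


def _split(amputed: AmputedSubset, spec: ImputationModelSpec):
    table = amputed.table
    X = _design(table, spec.predictors)
    y = pd.to_numeric(table[spec.target], errors="coerce").astype(float)
    obs = y.notna() & X.notna().all(axis=1)
    mis = amputed.mask
    return X[obs].to_numpy(), y[obs].to_numpy(), X[mis].to_numpy(), table.index[obs], table.index[mis]


def _complete(amputed: AmputedSubset, pooled: pd.Series) -> pd.DataFrame:
    out = amputed.table.copy()
    col = amputed.spec.target_variable
    if out[col].dtype == "Int64" and not pooled.empty:
        out[col] = out[col].astype(float)
    out.loc[pooled.index, col] = pooled
    return out


# -- ad-hoc strategies ------------------------------------------------------


def complete_case(amputed: AmputedSubset, model_vars=None):
    """Rows fully observed on the model variables, plus the excluded rows."""
    model_vars = list(model_vars) if model_vars is not None else list(_MODEL_VARS)
    present = [v for v in model_vars if v in amputed.table.columns]
    keep = amputed.table[present].notna().all(axis=1)
    excluded = list(amputed.table.index[~keep])
    return amputed.table[keep].copy(), excluded


def impute_cca(amputed: AmputedSubset, model_vars=None) -> ImputationResult:
    table, excluded = complete_case(amputed, model_vars)
    return ImputationResult(
        method="cca",
        completed_table=table,
        pooled=pd.Series(dtype=float),
        excluded_rows=excluded,
    )


def impute_mean(amputed: AmputedSubset) -> ImputationResult:
    """Every missing entry receives the mean of the observed target values."""
    col = amputed.spec.target_variable
    y = pd.to_numeric(amputed.table[col], errors="coerce").astype(float)
    if y.notna().sum() < 1:
        raise InsufficientDataError("no observed target values to average")
    pooled = pd.Series(float(y.mean()), index=amputed.table.index[amputed.mask])
    return ImputationResult(method="mean", completed_table=_complete(amputed, pooled), pooled=pooled)


def impute_locf(amputed: AmputedSubset, donor_week: str) -> ImputationResult:
    """Carry the same patient's earlier assessment forward.

    Rows whose donor value is also missing cannot be imputed; they are
    reported in ``excluded_rows`` and left missing in the completed table.
    """
    target = amputed.spec.target_variable
    if donor_week not in _WEEK_ORDER or _WEEK_ORDER[donor_week] >= _WEEK_ORDER[target]:
        raise ConfigurationError(
            f"LOCF donor {donor_week!r} must chronologically precede target {target!r}"
        )
    donors = pd.to_numeric(amputed.table[donor_week], errors="coerce").astype(float)
    rows = amputed.table.index[amputed.mask]
    have = donors[rows].notna()
    excluded = list(rows[~have])
    if excluded:
        logger.warning("LOCF: %d rows excluded (donor %s also missing)", len(excluded), donor_week)
    pooled = donors[rows[have]].copy()
    completed = _complete(amputed, pooled)
    return ImputationResult(
        method="locf", completed_table=completed, pooled=pooled, excluded_rows=excluded
    )


# -- single model-based imputation ------------------------------------------


def _make_estimator(model_kind: str, seed: int):
    scale = model_kind in ("knn", "svm_linear", "svm_rbf")
    if model_kind == "lr":
        model = LinearRegression()
    elif model_kind == "knn":
        model = KNeighborsRegressor()
    elif model_kind == "svm_linear":
        model = SVR(kernel="linear")
    elif model_kind == "svm_rbf":
        model = SVR(kernel="rbf")
    elif model_kind == "rf":
        model = RandomForestRegressor(random_state=seed)
    else:
        raise ConfigurationError(f"unknown single-imputation model {model_kind!r}")
    steps = ([("scale", StandardScaler())] if scale else []) + [("model", model)]
    return Pipeline(steps)


def tune_and_fit_single(model_kind, X_train, y_train, seed: int, grids=None):
    """5-fold CV grid search minimizing squared error; returns (fit, params)."""
    if len(y_train) < 10:
        raise InsufficientDataError(f"only {len(y_train)} training rows (need >= 10)")
    grids = grids if grids is not None else DEFAULT_GRIDS
    grid = grids.get(model_kind, {})
    est = _make_estimator(model_kind, seed)
    if grid:
        cv = KFold(n_splits=5, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="neg_mean_squared_error", n_jobs=1)
        search.fit(X_train, y_train)
        return search.best_estimator_, dict(search.best_params_)
    est.fit(X_train, y_train)
    return est, {}


def impute_single(
    amputed: AmputedSubset,
    model_kind: str,
    seed: int,
    spec: ImputationModelSpec | None = None,
    grids=None,
) -> ImputationResult:
    """Fit on the fully observed rows, predict the missing ones."""
    if model_kind not in SINGLE_KINDS:
        raise ConfigurationError(f"model_kind must be one of {SINGLE_KINDS}")
    spec = spec or default_model_spec(amputed.spec.target_variable)
    X_obs, y_obs, X_mis, _, idx_mis = _split(amputed, spec)
    fit, params = tune_and_fit_single(model_kind, X_obs, y_obs, seed, grids=grids)
    pred = np.clip(fit.predict(X_mis), 0.0, 50.0)
    pooled = pd.Series(pred, index=idx_mis)
    return ImputationResult(
        method=f"single_{model_kind}",
        completed_table=_complete(amputed, pooled),
        pooled=pooled,
        tuning=params,
    )


# -- multiple imputation -----------------------------------------------------


def _pmm_draw(rng, X_obs, y_obs, X_mis, donors: int) -> np.ndarray:
    """One predictive-mean-matching draw (type-1 matching, Bayesian beta)."""
    n, k = X_obs.shape
    Xo = np.column_stack([np.ones(n), X_obs])
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    xtx = Xo.T @ Xo
    ridge = 1e-10 * np.eye(k + 1)
    xtx_inv = np.linalg.inv(xtx + ridge * max(1.0, np.trace(xtx)))
    beta_hat = xtx_inv @ (Xo.T @ y_obs)
    resid = y_obs - Xo @ beta_hat
    dof = max(n - k - 1, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * xtx_inv
    cov = (cov + cov.T) / 2
    beta_star = rng.multivariate_normal(beta_hat, cov, method="svd")
    eta_obs = Xo @ beta_hat  # observed rows under the point estimate
    eta_mis = Xm @ beta_star  # missing rows under the parameter draw
    out = np.empty(len(X_mis))
    for i, e in enumerate(eta_mis):
        nearest = np.argpartition(np.abs(eta_obs - e), donors - 1)[:donors]
        out[i] = y_obs[nearest[rng.integers(donors)]]
    return out


def _rf_draw(rng, X_obs, y_obs, X_mis, n_trees: int) -> np.ndarray:
    """One mice-style random-forest draw: bootstrap, then leaf-donor sampling."""
    n = len(y_obs)
    boot = rng.integers(0, n, size=n)
    Xb, yb = X_obs[boot], y_obs[boot]
    forest = RandomForestRegressor(
        n_estimators=n_trees, min_samples_leaf=5, random_state=int(rng.integers(2**31))
    )
    forest.fit(Xb, yb)
    leaves_mis = forest.apply(X_mis)  # (n_mis, n_trees)
    leaves_obs = forest.apply(Xb)
    out = np.empty(len(X_mis))
    trees = rng.integers(n_trees, size=len(X_mis))
    for i, t in enumerate(trees):
        pool = yb[leaves_obs[:, t] == leaves_mis[i, t]]
        out[i] = pool[rng.integers(len(pool))] if len(pool) else yb[rng.integers(n)]
    return out


def impute_multiple(
    amputed: AmputedSubset,
    method: str,
    seed: int,
    m: int = 25,
    donors: int = 5,
    n_trees: int = 10,
    spec: ImputationModelSpec | None = None,
) -> ImputationResult:
    """m-fold multiple imputation pooled by the per-entry arithmetic mean."""
    if method not in MULTI_KINDS:
        raise ConfigurationError(f"method must be one of {MULTI_KINDS}")
    if m < 2:
        raise ConfigurationError(f"m must be >= 2, got {m}")
    spec = spec or default_model_spec(amputed.spec.target_variable)
    X_obs, y_obs, X_mis, _, idx_mis = _split(amputed, spec)
    if method == "pmm" and donors > len(y_obs):
        raise DonorPoolError(f"d={donors} donors requested but only {len(y_obs)} observed rows")

    draws = np.empty((len(idx_mis), m))
    if method == "norm_predict":
        # deterministic least-squares prediction: all m draws identical
        logger.info("norm_predict is degenerate: all %d draws coincide", m)
        Xo = np.column_stack([np.ones(len(X_obs)), X_obs])
        Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
        beta, *_ = np.linalg.lstsq(Xo, y_obs, rcond=None)
        pred = np.clip(Xm @ beta, 0.0, 50.0)
        draws[:] = pred[:, None]
    else:
        for d, child in enumerate(np.random.SeedSequence(seed).spawn(m)):
            rng = np.random.default_rng(child)
            if method == "pmm":
                draws[:, d] = _pmm_draw(rng, X_obs, y_obs, X_mis, donors)
            else:
                draws[:, d] = _rf_draw(rng, X_obs, y_obs, X_mis, n_trees)

    draws_df = pd.DataFrame(draws, index=idx_mis, columns=[f"m{j+1}" for j in range(m)])
    pooled = draws_df.mean(axis=1)
    return ImputationResult(
        method=f"multi_{method}",
        completed_table=_complete(amputed, pooled),
        pooled=pooled,
        draws=draws_df,
        tuning={"m": m, **({"donors": donors} if method == "pmm" else {}),
                **({"n_trees": n_trees} if method == "rf" else {})},
    )


# -- dispatcher --------------------------------------------------------------


def locf_donor_for(target: str) -> str:
    """Default LOCF donor week: the closest earlier trial assessment."""
    return {"lems_w52": "lems_w26", "lems_w26": "lems_w16"}.get(target, "lems_w16")


def run_method(
    amputed: AmputedSubset,
    method: str,
    seed: int,
    m: int = 25,
    grids=None,
    model_vars=None,
) -> ImputationResult:
    """Apply one named strategy to an amputed subset."""
    if method == "cca":
        return impute_cca(amputed, model_vars=model_vars)
    if method == "mean":
        return impute_mean(amputed)
    if method == "locf":
        return impute_locf(amputed, locf_donor_for(amputed.spec.target_variable))
    if method.startswith("single_"):
        return impute_single(amputed, method.removeprefix("single_"), seed, grids=grids)
    if method.startswith("multi_"):
        return impute_multiple(amputed, method.removeprefix("multi_"), seed, m=m)
    raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
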