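"""Imputation strategies: copy semantics, donor closure, model recovery."""

import numpy as np
import pandas as pd
import pytest

from scimiss import (
    ImputationModelSpec,
    MissingnessSpec,
    ampute,
    complete_case,
    impute_locf,
    impute_mean,
    impute_multiple,
    impute_single,
    run_method,
)
from scimiss.errors import ConfigurationError, DonorPoolError
from scimiss.imputation import default_model_spec, impute_cca


def _toy_amputed(values, mask_rows, target="lems_w0", extra=None):
    """Small amputed table with explicit truths for the masked rows."""
    n = len(values)
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "patient_id": [f"t{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.uniform(20, 60, size=n),
            "nli": rng.choice(["cervical", "thoracic"], size=n),
            "ais_grade": rng.choice(list("ABCD"), size=n),
            "lems_w0": np.asarray(values, dtype=float),
            "lems_w16": np.asarray(values, dtype=float),
            "lems_w26": np.asarray(values, dtype=float),
            "lems_w52": np.asarray(values, dtype=float),
        }
    )
    if extra:
        for k, v in extra.items():
            table[k] = v
    amp = ampute(table, MissingnessSpec(target, "MCAR", rate=len(mask_rows) / n), seed=0)
    # rewrite the mask deterministically to the requested rows
    amp.mask[:] = False
    amp.mask[list(mask_rows)] = True
    amp.vault = table.loc[list(mask_rows), target].astype(float)
    amp.table = table.copy()
    amp.table.loc[list(mask_rows), target] = np.nan
    return amp, table


def test_mean_imputation_examples():
    amp, _ = _toy_amputed([0, 0, 30, 10, 10], mask_rows=[3, 4])
    res = impute_mean(amp)
    # observed {0, 0, 30} -> every imputation is 10
    assert (res.pooled == 10.0).all()
    completed = res.completed_table["lems_w0"].astype(float)
    assert completed.notna().all()


def test_mean_imputation_constant_observed():
    amp, _ = _toy_amputed([7, 7, 7, 1, 2], mask_rows=[3, 4])
    res = impute_mean(amp)
    assert (res.pooled == 7.0).all()
    assert res.pooled.var() == 0.0


def test_mean_imputation_shifts_zero_inflated_distribution(amputed_w0_mnar):
    """KS rejects true vs mean-imputed for heavily zero-inflated LEMS."""
    from scimiss import ks_two_sample

    res = impute_mean(amputed_w0_mnar)
    truth_full = amputed_w0_mnar.subset.table["lems_w0"].astype(float)
    imputed_full = res.completed_table["lems_w0"].astype(float)
    _, p = ks_two_sample(truth_full.to_numpy(), imputed_full.to_numpy())
    assert p < 0.05


def test_locf_copies_donor_values(subset):
    amp = ampute(subset, MissingnessSpec("lems_w52", "MCAR"), seed=9)
    res = impute_locf(amp, "lems_w26")
    donors = amp.table.loc[res.pooled.index, "lems_w26"].astype(float)
    assert (res.pooled == donors).all()
    # rows with a missing donor are excluded, not imputed
    rows = amp.table.index[amp.mask]
    missing_donor = amp.table.loc[rows, "lems_w26"].isna()
    assert set(res.excluded_rows) == set(rows[missing_donor])
    assert res.completed_table.loc[res.excluded_rows, "lems_w52"].isna().all()


def test_locf_donor_must_precede_target(subset):
    amp_w52 = ampute(subset, MissingnessSpec("lems_w52", "MCAR"), seed=9)
    with pytest.raises(ConfigurationError):
        impute_locf(amp_w52, "lems_w52")


def test_locf_time_shift_variant(cohort):
    """Week-26 target with week-16 donor is a valid configuration."""
    from scimiss import default_generator_config, draw_subset, generate_cohort, EMPIRICAL_GRADES

    clean = generate_cohort(default_generator_config(w26_missing_rate=0.0), seed=2)
    sub = draw_subset(clean, EMPIRICAL_GRADES, 500, seed=3)
    amp = ampute(sub, MissingnessSpec("lems_w26", "MCAR"), seed=4)
    res = impute_locf(amp, "lems_w16")
    assert res.excluded_rows == []
    donors = amp.table.loc[res.pooled.index, "lems_w16"].astype(float)
    assert (res.pooled == donors).all()


def test_complete_case_scoping(amputed_w0_mnar):
    table, excluded = complete_case(amputed_w0_mnar, ["lems_w0", "lems_w52", "sex"])
    assert len(table) == 350  # 500 - 150 amputed
    assert len(excluded) == 150
    # rows missing only on a variable outside model_vars are retained
    t2, ex2 = complete_case(amputed_w0_mnar, ["lems_w52", "sex"])
    assert len(t2) == 500 and ex2 == []


def test_complete_case_identity_when_no_missing(subset):
    amp = ampute(subset, MissingnessSpec("lems_w0", "MCAR"), seed=1)
    amp.table = subset.table.copy()  # undo the blanking
    table, excluded = complete_case(amp, ["lems_w0", "sex"])
    assert len(table) == 500 and excluded == []


def test_single_lr_recovers_noiseless_linear_model():
    rng = np.random.default_rng(1)
    n = 200
    age = rng.uniform(20, 60, size=n)
    target = 3.0 + 0.5 * age  # purely linear in a numeric predictor
    amp, table = _toy_amputed(np.clip(target, 0, None), mask_rows=range(0, 40))
    amp.table["age"] = age
    amp.vault = pd.Series(target[:40], index=range(40))
    spec = ImputationModelSpec("lems_w0", ("age",), outcome_excluded=True)
    res = impute_single(amp, "lr", seed=0, spec=spec)
    np.testing.assert_allclose(res.pooled.to_numpy(), np.clip(target[:40], 0, 50), atol=1e-8)


def test_knn_k1_nearest_neighbor_identity():
    # an amputed row duplicating an observed row on all predictors
    age = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 25.0, 35.0, 45.0, 55.0, 30.0])
    values = np.arange(12, dtype=float)
    amp, table = _toy_amputed(values, mask_rows=[11])
    amp.table["age"] = age
    spec = ImputationModelSpec("lems_w0", ("age",), outcome_excluded=True)
    res = impute_single(amp, "knn", seed=0, spec=spec, grids={"knn": {"model__n_neighbors": [1]}})
    assert res.pooled.iloc[0] == values[1]  # row 1 shares age 30.0


def test_rf_predictions_within_observed_range(amputed_w0_mnar):
    res = impute_single(
        amputed_w0_mnar, "rf", seed=0,
        grids={"rf": {"model__n_estimators": [50], "model__min_samples_leaf": [5]}},
    )
    observed = amputed_w0_mnar.table["lems_w0"].dropna().astype(float)
    assert res.pooled.between(observed.min(), observed.max()).all()


def test_non_interference_all_strategies(amputed_w52_mcar):
    """No strategy may alter a non-amputed entry."""
    untouched = ~amputed_w52_mcar.mask
    original = amputed_w52_mcar.table.loc[untouched, "lems_w52"].astype(float)
    for method in ("mean", "locf", "single_lr", "multi_pmm", "multi_norm_predict", "multi_rf"):
        res = run_method(amputed_w52_mcar, method, seed=1, m=3)
        now = res.completed_table.loc[untouched, "lems_w52"].astype(float)
        pd.testing.assert_series_equal(now, original, check_dtype=False)


@pytest.mark.parametrize("method", ["pmm", "rf"])
def test_donor_closure(amputed_w0_mnar, method):
    """Every pmm / multi-rf draw is an observed donor value."""
    res = impute_multiple(amputed_w0_mnar, method, seed=2, m=5)
    observed = set(amputed_w0_mnar.table["lems_w0"].dropna().astype(float))
    drawn = set(np.asarray(res.draws).ravel())
    assert drawn <= observed


@pytest.mark.parametrize("method", ["pmm", "norm_predict", "rf"])
def test_pooling_identity(amputed_w0_mnar, method):
    res = impute_multiple(amputed_w0_mnar, method, seed=3, m=4)
    pd.testing.assert_series_equal(res.pooled, res.draws.mean(axis=1), check_names=False)


def test_norm_predict_degenerate_draws(amputed_w0_mnar):
    res = impute_multiple(amputed_w0_mnar, "norm_predict", seed=4, m=6)
    assert (res.draws.nunique(axis=1) == 1).all()


def test_pmm_accuracy_on_linear_data():
    """pmm pooled MAE below 3x the noise SD on data from a linear model."""
    rng = np.random.default_rng(5)
    n = 1000
    age = rng.uniform(20, 60, size=n)
    noise_sd = 0.1
    target = 2.0 * age + rng.normal(0, noise_sd, size=n)
    amp, _ = _toy_amputed(target, mask_rows=range(300))
    amp.table["age"] = age
    amp.vault = pd.Series(target[:300], index=range(300))
    spec = ImputationModelSpec("lems_w0", ("age",), outcome_excluded=True)
    res = impute_multiple(amp, "pmm", seed=6, m=25, spec=spec)
    mae = float(np.mean(np.abs(res.pooled.to_numpy() - target[:300])))
    assert mae < 3 * noise_sd


def test_outcome_exclusion_invariant():
    with pytest.raises(ConfigurationError):
        ImputationModelSpec("lems_w0", ("lems_w52", "age"), outcome_excluded=False)
    spec = default_model_spec("lems_w0")
    assert "lems_w52" not in spec.predictors and spec.outcome_excluded
    spec_out = default_model_spec("lems_w52")
    assert "lems_w0" in spec_out.predictors


def test_donor_pool_error():
    amp, _ = _toy_amputed([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], mask_rows=[0, 1, 2])
    with pytest.raises(DonorPoolError):
        impute_multiple(amp, "pmm", seed=0, m=2, donors=10)


def test_cca_result_has_no_pooled_values(amputed_w0_mnar):
    res = impute_cca(amputed_w0_mnar)
    assert res.pooled.empty
    assert len(res.excluded_rows) == 150
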