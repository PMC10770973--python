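import numpy as np
import pandas as pd
import pytest

from scimiss import (
    EMPIRICAL_GRADES,
    MissingnessSpec,
    ampute,
    default_generator_config,
    draw_subset,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic complete-case cohort (n = 546)."""
    return generate_cohort(default_generator_config(), seed=11)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment checks."""
    return generate_cohort(default_generator_config(n_patients=100_000), seed=12)


@pytest.fixture(scope="session")
def subset(cohort):
    """One empirical-composition bootstrap subset of n = 500."""
    return draw_subset(cohort, EMPIRICAL_GRADES, 500, seed=7)


@pytest.fixture(scope="session")
def amputed_w0_mnar(subset):
    return ampute(subset, MissingnessSpec("lems_w0", "MNAR"), seed=3)


@pytest.fixture(scope="session")
def amputed_w52_mcar(subset):
    return ampute(subset, MissingnessSpec("lems_w52", "MCAR"), seed=4)


@pytest.fixture()
def linear_cohort():
    """A cohort whose chronic score follows a known linear model.

    lems_w52 = b0 + b1*lems_w0 + b_B/C/D + b_nli + b_age*age + b_sex + noise,
    used for parameter-recovery checks of the analysis model.
    """
    rng = np.random.default_rng(7)
    n = 5000
    truth = {
        "intercept": 2.0, "lems_w0": 0.8, "ais_B": 4.0, "ais_C": 10.0,
        "ais_D": 16.0, "nli_thoracic": 1.5, "age": -0.05, "sex_male": 0.5,
    }
    grade = rng.choice(list("ABCD"), size=n)
    sex = rng.choice(["female", "male"], size=n)
    nli = rng.choice(["cervical", "thoracic"], size=n)
    age = rng.uniform(16, 80, size=n)
    w0 = rng.uniform(0, 30, size=n)
    y = (
        truth["intercept"]
        + truth["lems_w0"] * w0
        + truth["ais_B"] * (grade == "B")
        + truth["ais_C"] * (grade == "C")
        + truth["ais_D"] * (grade == "D")
        + truth["nli_thoracic"] * (nli == "thoracic")
        + truth["age"] * age
        + truth["sex_male"] * (sex == "male")
        + rng.normal(0, 3.0, size=n)
    )
    table = pd.DataFrame(
        {
            "patient_id": [f"L{i}" for i in range(n)],
            "sex": sex, "age": age, "nli": nli, "ais_grade": grade,
            "lems_w0": w0, "lems_w16": w0, "lems_w26": w0, "lems_w52": y,
        }
    )
    return table, truth
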