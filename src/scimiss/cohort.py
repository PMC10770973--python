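"""Synthetic SCI cohort generation and the cohort CSV schema.

A cohort is a pandas DataFrame with columns

    patient_id, sex, age, nli, ais_grade, lems_w0, lems_w16, lems_w26, lems_w52

LEMS columns are pandas nullable integers (``Int64``) in [0, 50]; a missing
week-26 score is the only missingness the generator itself produces. On
disk the schema is plain CSV with missing entries encoded as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig, default_generator_config
from .errors import CohortValidationError
from ._util import GRADES, LEMS_COLUMNS

SCHEMA_COLUMNS = ["patient_id", "sex", "age", "nli", "ais_grade", *LEMS_COLUMNS]


@dataclass
class Cohort:
    """A cohort table plus generation provenance (config digest and seed)."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> Cohort:
    """Sample a synthetic cohort.

    Hierarchical model: AIS grade ~ grade_probs; sex, NLI ~ independent
    Bernoulli; age ~ normal truncated to [age_min, age_max]; week-0 LEMS is
    zero with a grade-specific probability, otherwise a discretized gamma
    clipped to [0, 50]; a latent recovery gain (zero-inflated gamma, grade
    specific) is realized fractionally at week 16 and fully at week 26;
    week 52 adds small rounded-normal plateau noise to week 26, except that
    patients with a week-26 score of 0 stay at 0 (complete injuries do not
    spontaneously recover on the plateau). Week-26 scores are then masked
    MCAR at ``w26_missing_rate``.

    Identical ``(config, seed)`` yields an identical table.
    """
    if config is None:
        config = default_generator_config()
    rng = np.random.default_rng(seed)
    n = config.n_patients

    grades = rng.choice(np.array(GRADES), size=n, p=config.grade_probs.as_tuple())
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    nli = np.where(rng.random(n) < config.p_cervical, "cervical", "thoracic")

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    w0 = np.zeros(n)
    gain = np.zeros(n)
    for g in GRADES:
        mask = grades == g
        m = int(mask.sum())
        if m == 0:
            continue
        t = config.trajectories[g]
        nonzero = rng.random(m) >= t.p_zero_w0
        draw = rng.gamma(t.w0_shape, t.w0_mean / t.w0_shape, size=m)
        w0[mask] = np.where(nonzero, draw, 0.0)
        has_gain = rng.random(m) < t.p_gain
        gdraw = rng.gamma(t.gain_shape, t.gain_mean / t.gain_shape, size=m)
        gain[mask] = np.where(has_gain, gdraw, 0.0)

    w0 = np.clip(np.rint(w0), 0, 50)
    w16 = np.clip(w0 + np.rint(config.w16_fraction * gain), 0, 50)
    w26 = np.clip(w0 + np.rint(gain), 0, 50)
    delta = np.rint(rng.normal(config.plateau_gain_mean, config.plateau_gain_sd, size=n))
    w52 = np.where(w26 > 0, np.clip(w26 + delta, 0, 50), 0.0)

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "nli": nli,
            "ais_grade": grades,
            "lems_w0": pd.array(w0.astype(int), dtype="Int64"),
            "lems_w16": pd.array(w16.astype(int), dtype="Int64"),
            "lems_w26": pd.array(w26.astype(int), dtype="Int64"),
            "lems_w52": pd.array(w52.astype(int), dtype="Int64"),
        }
    )
    if config.w26_missing_rate > 0:
        missing = rng.random(n) < config.w26_missing_rate
        table.loc[missing, "lems_w26"] = pd.NA

    provenance = {"config_digest": config.digest(), "seed": int(seed), "version": config.version}
    return Cohort(table=table, provenance=provenance)


def validate_cohort(table: pd.DataFrame) -> list[tuple[object, str]]:
    """Return (row_label, message) schema violations; empty list if valid."""
    violations: list[tuple[object, str]] = []
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing_cols:
        return [("-", f"missing columns: {missing_cols}")]

    dup = table["patient_id"][table["patient_id"].duplicated()]
    for idx in dup.index:
        violations.append((idx, f"duplicate patient_id {table.at[idx, 'patient_id']!r}"))
    for idx in table.index[~table["sex"].isin(["male", "female"])]:
        violations.append((idx, f"invalid sex {table.at[idx, 'sex']!r}"))
    for idx in table.index[~table["nli"].isin(["cervical", "thoracic"])]:
        violations.append((idx, f"invalid nli {table.at[idx, 'nli']!r}"))
    for idx in table.index[~table["ais_grade"].isin(list(GRADES))]:
        violations.append((idx, f"invalid ais_grade {table.at[idx, 'ais_grade']!r}"))
    age = pd.to_numeric(table["age"], errors="coerce")
    for idx in table.index[~(age > 0)]:
        violations.append((idx, f"age must be positive, got {table.at[idx, 'age']!r}"))
    for col in LEMS_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        observed = table[col].notna()
        bad = observed & (vals.isna() | (vals < 0) | (vals > 50) | (vals != vals.round()))
        for idx in table.index[bad]:
            violations.append((idx, f"{col} must be an integer in [0, 50], got {table.at[idx, col]!r}"))
    return violations


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (missing entries = empty fields)."""
    table = pd.read_csv(
        path,
        dtype={c: "Int64" for c in LEMS_COLUMNS} | {"patient_id": str},
    )
    violations = validate_cohort(table)
    if violations:
        raise CohortValidationError(violations)
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
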