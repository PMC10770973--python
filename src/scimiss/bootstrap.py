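"""Stratified bootstrap subsets with fixed AIS-grade composition.

Subsets are drawn with replacement *within* each grade stratum so the
realized composition always equals the target counts exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GradeDistribution, BALANCED_GRADES, EMPIRICAL_GRADES
from .cohort import Cohort, write_cohort_csv
from .errors import StratificationError
from ._util import GRADES, largest_remainder


@dataclass
class BootstrapSubset:
    """A fixed-composition bootstrap sample of a cohort."""

    table: pd.DataFrame
    composition_label: str
    grade_counts: dict[str, int]
    seed: int

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path, manifest_path=None) -> None:
        write_cohort_csv(self.table, path)
        if manifest_path is not None:
            Path(manifest_path).write_text(
                json.dumps(
                    {
                        "composition_label": self.composition_label,
                        "grade_counts": self.grade_counts,
                        "seed": self.seed,
                    },
                    indent=2,
                )
            )


def grade_counts_for(n: int, dist: GradeDistribution) -> dict[str, int]:
    """Integer per-grade target counts summing exactly to ``n``.

    Largest-remainder rounding of ``n * p_g``; deterministic. A zero count
    paired with a nonzero proportion triggers a warning, not an error.
    """
    if n < 4:
        raise ValueError(f"subset size must be >= 4, got {n}")
    raw = np.array(dist.as_tuple()) * n
    counts = largest_remainder(raw, n)
    for g, c, p in zip(GRADES, counts, dist.as_tuple()):
        if c == 0 and p > 0:
            warnings.warn(
                f"grade {g} has nonzero proportion {p} but a target count of 0 at n={n}",
                stacklevel=2,
            )
    return dict(zip(GRADES, (int(c) for c in counts)))


def composition_label_for(dist: GradeDistribution) -> str:
    if dist == BALANCED_GRADES:
        return "balanced"
    if dist == EMPIRICAL_GRADES:
        return "empirical"
    return "custom"


def draw_subset(
    cohort: Cohort | pd.DataFrame,
    dist: GradeDistribution,
    n: int,
    seed: int,
    composition_label: str | None = None,
) -> BootstrapSubset:
    """Sample ``n`` rows with replacement, stratified by AIS grade.

    Each grade stratum is resampled to its ``grade_counts_for`` target;
    reproducible under equal seed. An empty stratum with a positive target
    raises :class:`StratificationError` naming the grade.
    """
    table = cohort.table if isinstance(cohort, Cohort) else cohort
    counts = grade_counts_for(n, dist)
    rng = np.random.default_rng(seed)
    parts = []
    for g in GRADES:
        k = counts[g]
        if k == 0:
            continue
        stratum = table.index[table["ais_grade"] == g]
        if len(stratum) == 0:
            raise StratificationError(
                f"cohort has no records of AIS grade {g} but the target count is {k}"
            )
        take = rng.integers(0, len(stratum), size=k)
        parts.append(table.loc[stratum[take]])
    sub = pd.concat(parts, axis=0).reset_index(drop=True)
    return BootstrapSubset(
        table=sub,
        composition_label=composition_label or composition_label_for(dist),
        grade_counts=counts,
        seed=int(seed),
    )
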