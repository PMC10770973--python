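"""Controlled introduction of missingness (amputation) under MCAR/MAR/MNAR.

Each mechanism blanks exactly ``round(rate * n)`` entries of one LEMS
variable and vaults the true values for later scoring:

MCAR
    a simple random sample of rows.
MAR
    missingness depends on sex; males are ``mar_ratio`` (default 2) times
    more likely to have the value missing than females.
MNAR
    missingness depends on the value itself; entries above the variable's
    empirical 30th percentile are ``mnar_ratio`` (default 4) times more
    likely to be missing than entries at or below it. With zero-inflated
    LEMS the threshold is frequently 0, making "high" any nonzero score.

"k times more likely" is realized as a ratio of per-entry missingness
probabilities with an exact total: probabilities are solved so the expected
count equals k, converted to per-group integer counts by largest-remainder
rounding, then rows are sampled uniformly within groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSubset
from .errors import ConfigurationError, FeasibilityError, PreexistingMissingError
from ._util import largest_remainder

logger = logging.getLogger(__name__)

PATTERNS = ("MCAR", "MAR", "MNAR")
AMPUTABLE = ("lems_w0", "lems_w26", "lems_w52")


@dataclass(frozen=True)
class MissingnessSpec:
    """What to ampute and under which mechanism."""

    target_variable: str
    pattern: str
    rate: float = 0.30
    mar_ratio: float = 2.0
    mnar_ratio: float = 4.0
    mnar_percentile: float = 30.0

    def __post_init__(self):
        if self.target_variable not in AMPUTABLE:
            raise ConfigurationError(
                f"target_variable must be one of {AMPUTABLE}, got {self.target_variable!r}"
            )
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if not 0.0 < self.rate < 1.0:
            raise ConfigurationError(f"rate must lie in (0, 1), got {self.rate}")
        if self.mar_ratio < 1 or self.mnar_ratio < 1:
            raise ConfigurationError("likelihood ratios must be >= 1")
        if not 0.0 < self.mnar_percentile < 100.0:
            raise ConfigurationError("mnar_percentile must lie in (0, 100)")


@dataclass
class AmputedSubset:
    """A bootstrap subset with blanked target entries and a truth vault."""

    table: pd.DataFrame
    mask: pd.Series  # boolean, True = amputed
    vault: pd.Series  # row label -> true (pre-amputation) value
    spec: MissingnessSpec
    seed: int
    subset: BootstrapSubset | None = None
    fallback_mcar: bool = field(default=False)

    @property
    def n_amputed(self) -> int:
        return int(self.mask.sum())

    def to_csv(self, path, vault_path=None, manifest_path=None) -> None:
        self.table.to_csv(path, index=False)
        if vault_path is not None:
            self.vault.rename("true_value").rename_axis("row").to_csv(vault_path)
        if manifest_path is not None:
            Path(manifest_path).write_text(
                json.dumps({"spec": self.spec.__dict__, "seed": self.seed}, indent=2)
            )


def group_missing_counts(group_sizes, ratio: float, k_total: int):
    """Split ``k_total`` missing entries over groups with a probability ratio.

    ``group_sizes[0]`` is the elevated group: its per-entry missingness
    probability is ``ratio`` times that of the others. Solves
    ``ratio * n_high * p + sum(n_low) * p = k_total`` for the base
    probability p, then allocates integer counts by largest remainder.
    """
    sizes = np.asarray(group_sizes, dtype=int)
    if k_total > sizes.sum():
        raise FeasibilityError(f"k_total={k_total} exceeds population {sizes.sum()}")
    weights = np.ones(len(sizes))
    weights[0] = ratio
    p_low = k_total / float((weights * sizes).sum())
    if ratio * p_low > 1.0 + 1e-12:
        raise FeasibilityError(
            f"requested ratio {ratio} with k_total={k_total} implies a per-entry "
            f"probability above 1 in the elevated group"
        )
    raw = sizes * weights * p_low
    counts = largest_remainder(raw, k_total)
    if np.any(counts > sizes):
        raise FeasibilityError(f"allocation {counts.tolist()} exceeds group sizes {sizes.tolist()}")
    return counts


def ampute(subset: BootstrapSubset | pd.DataFrame, spec: MissingnessSpec, seed: int) -> AmputedSubset:
    """Blank ``round(rate * n)`` entries of the target variable.

    The target must be fully observed beforehand. MNAR with a degenerate
    value distribution (empty high group) falls back to MCAR with a logged
    warning. Reproducible under equal seed.
    """
    table = subset.table if isinstance(subset, BootstrapSubset) else subset
    col = spec.target_variable
    if table[col].isna().any():
        raise PreexistingMissingError(
            f"{col} already has {int(table[col].isna().sum())} missing entries"
        )
    n = len(table)
    k = int(np.rint(spec.rate * n))
    rng = np.random.default_rng(seed)
    values = table[col].to_numpy(dtype=float)
    fallback = False

    if spec.pattern == "MCAR":
        pos = rng.choice(n, size=k, replace=False)
    elif spec.pattern == "MAR":
        is_male = (table["sex"] == "male").to_numpy()
        pos = _two_group_sample(rng, is_male, spec.mar_ratio, k)
    else:  # MNAR
        q = np.percentile(values, spec.mnar_percentile)
        is_high = values > q
        if not is_high.any():
            logger.warning(
                "MNAR degenerate: no value above the %gth percentile (q=%g); falling back to MCAR",
                spec.mnar_percentile,
                q,
            )
            fallback = True
            pos = rng.choice(n, size=k, replace=False)
        else:
            pos = _two_group_sample(rng, is_high, spec.mnar_ratio, k)

    mask = pd.Series(False, index=table.index)
    mask.iloc[pos] = True
    vault = table[col][mask].copy()
    amputed = table.copy()
    amputed.loc[mask, col] = pd.NA
    return AmputedSubset(
        table=amputed,
        mask=mask,
        vault=vault,
        spec=spec,
        seed=int(seed),
        subset=subset if isinstance(subset, BootstrapSubset) else None,
        fallback_mcar=fallback,
    )


def _two_group_sample(rng, in_high: np.ndarray, ratio: float, k: int) -> np.ndarray:
    """Sample k positions: high group ``ratio`` times likelier per entry."""
    idx_high = np.flatnonzero(in_high)
    idx_low = np.flatnonzero(~in_high)
    counts = group_missing_counts([len(idx_high), len(idx_low)], ratio, k)
    take_high = rng.choice(idx_high, size=counts[0], replace=False)
    take_low = rng.choice(idx_low, size=counts[1], replace=False)
    return np.concatenate([take_high, take_low])


def verify_mechanism(amputed: AmputedSubset, variables):
    """Little's MCAR test over the given (numerically encoded) variables."""
    from .little import little_mcar_test
    from ._util import encode_numeric

    data = encode_numeric(amputed.table, variables)
    return little_mcar_test(data)
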