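"""Shared helpers: seed derivation and numeric encoding of categoricals."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

GRADES = ("A", "B", "C", "D")
LEMS_COLUMNS = ("lems_w0", "lems_w16", "lems_w26", "lems_w52")

#: Numeric codes used whenever a categorical column feeds a numeric procedure
#: (Little's test, EM). Binary columns -> {0, 1}; AIS grade -> ordinal 1-4.
SEX_CODES = {"female": 0, "male": 1}
NLI_CODES = {"cervical": 0, "thoracic": 1}
GRADE_CODES = {"A": 1, "B": 2, "C": 3, "D": 4}


def derive_seed(*parts) -> int:
    """Stable 31-bit seed from an arbitrary tuple of labels.

    Used for the per-cell seed policy: seeds depend only on the coordinates
    of a computation, never on execution order, so any cell can be recomputed
    in isolation.
    """
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def encode_numeric(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Return a float-valued frame with categoricals numerically encoded.

    Missing entries stay NaN. Unknown columns pass through unchanged
    (they must already be numeric).
    """
    out = {}
    for col in columns:
        s = table[col]
        if col == "sex":
            out[col] = s.map(SEX_CODES).astype(float)
        elif col == "nli":
            out[col] = s.map(NLI_CODES).astype(float)
        elif col == "ais_grade":
            out[col] = s.map(GRADE_CODES).astype(float)
        else:
            out[col] = pd.to_numeric(s, errors="coerce").astype(float)
    return pd.DataFrame(out, index=table.index)


def largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``raw`` (>= 0).

    Floors each share and hands the remaining units to the largest
    fractional remainders; ties break toward the lowest index, so the
    allocation is deterministic.
    """
    raw = np.asarray(raw, dtype=float)
    base = np.floor(raw).astype(int)
    short = int(total - base.sum())
    if short > 0:
        remainders = raw - base
        # stable sort descending by remainder, ascending by index on ties
        order = np.lexsort((np.arange(raw.size), -remainders))
        base[order[:short]] += 1
    elif short < 0:
        remainders = raw - base
        order = np.lexsort((np.arange(raw.size), remainders))
        base[order[: -short]] -= 1
    return base
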