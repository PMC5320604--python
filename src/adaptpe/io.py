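"""Reading and writing the package's tabular formats.

Trial tables are CSV with the fixed header
``agent_id,session,block,trial,dist_id,ev,sd,cue_level,is_control,reward,prediction,missed,pe,payoff``
and empty strings for missing values.  Schema violations are reported with
1-based data row numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "TrialTableError"]


class TrialTableError(ValueError):
    """A trial-table file violated the schema."""


_BOUNDED = ("reward", "prediction")  # must lie in [0, 100] when present


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"table is missing columns: {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`TrialTableError` naming every missing column and every
    out-of-range value with its row number.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"{path}: file is empty") from None
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    if table.empty:
        raise TrialTableError(f"{path}: table has no rows")

    errors = []
    for col in _BOUNDED:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < 0) | (vals > 100)]
        for i in bad:
            errors.append(
                f"row {i + 1}: {col}={table.loc[i, col]} outside [0, 100]"
            )
    for col in ("is_control", "missed"):
        if not table[col].map(lambda v: isinstance(v, (bool, np.bool_))).all():
            coerced = table[col].astype(str).str.lower()
            if not coerced.isin(["true", "false"]).all():
                bad = table.index[~coerced.isin(["true", "false"])]
                errors.extend(
                    f"row {i + 1}: {col}={table.loc[i, col]!r} is not boolean"
                    for i in bad[:10]
                )
            else:
                table[col] = coerced == "true"
    if (table["session"] < 1).any() or (table["trial"] < 1).any():
        bad = table.index[(table["session"] < 1) | (table["trial"] < 1)]
        errors.extend(f"row {i + 1}: session/trial must be >= 1" for i in bad)
    if errors:
        raise TrialTableError(f"{path}: " + "; ".join(errors))
    return table[TRIAL_COLUMNS]
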