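"""Reading and writing trial tables (CSV with the TrialRecord schema).

Missing values (RT on reproduction trials, reproduction on decision
trials, arrowhead outside Müller-Lyer) are written as empty cells and read
back as missing, so a write/read round trip is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "SchemaError"]

_STRING_COLS = ["bias_source", "bias_direction", "true_category", "task", "choice"]
_FLOAT_COLS = ["arrowhead_px", "target_px", "rt_s", "reproduction_px", "points_lost"]
_INT_COLS = ["block_index", "trial_index"]


class SchemaError(ValueError):
    """A trial table violates the TrialRecord schema."""


def _check_schema(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    table = table[TRIAL_COLUMNS].copy()

    bad_task = ~table["task"].isin(["decision", "reproduction"])
    if bad_task.any():
        raise SchemaError(f"invalid task at rows {list(table.index[bad_task][:5])}")
    dec = table["task"] == "decision"
    no_choice = dec & table["choice"].isna()
    if no_choice.any():
        raise SchemaError(f"decision trials without choice at rows {list(table.index[no_choice][:5])}")
    stray_repro = dec & table["reproduction_px"].notna()
    if stray_repro.any():
        raise SchemaError(f"reproduction_px on decision trials at rows {list(table.index[stray_repro][:5])}")
    stray = ~dec & (table["choice"].notna() | table["rt_s"].notna())
    if stray.any():
        raise SchemaError(f"choice/rt on reproduction trials at rows {list(table.index[stray][:5])}")
    return table


def write_trials(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a trial table to CSV (UTF-8, empty string for missing).

    When ``metadata`` is given (design, observer parameters, seeds), it is
    written as a JSON sidecar next to the CSV (``<path>.meta.json``).
    """
    path = Path(path)
    table = _check_schema(table)
    table.to_csv(path, index=False, na_rep="")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, default=str))


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`."""
    table = pd.read_csv(
        path,
        dtype={c: "string" for c in _STRING_COLS},
        keep_default_na=True,
    )
    table = _check_schema(table)
    for col in _STRING_COLS:
        table[col] = table[col].astype(object).where(table[col].notna(), None)
    for col in _FLOAT_COLS:
        table[col] = pd.to_numeric(table[col], errors="coerce").astype(float)
    for col in _INT_COLS:
        table[col] = pd.to_numeric(table[col]).astype(np.int64)
    return table
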