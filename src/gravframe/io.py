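"""Trial-table CSV I/O with strict schema checking.

Schema (long format, one row per presentation):
``neuron_id, condition_id, tilt_deg, screen_orientation_deg, repetition,
rate_spk_s``.  Rates are spikes/s and must be non-negative.  Unknown extra
columns are tolerated with a warning; missing or malformed required columns
are errors.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import TRIAL_COLUMNS

_INT_COLUMNS = ("neuron_id", "condition_id", "repetition")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}")
        table = table[list(TRIAL_COLUMNS)]
    for col in TRIAL_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & table[col].notna().to_numpy())
        if table[col].isna().any() or bad.size:
            rows = np.flatnonzero(vals.isna().to_numpy())[:5] + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric or missing {col} near line(s) {rows.tolist()}")
        table[col] = vals
    if (table["rate_spk_s"] < 0).any():
        rows = (np.flatnonzero((table["rate_spk_s"] < 0).to_numpy())[:5] + 2).tolist()
        raise ValueError(f"{path}: negative rate_spk_s at line(s) {rows}")
    table[list(_INT_COLUMNS)] = table[list(_INT_COLUMNS)].astype(int)
    return table.reset_index(drop=True)


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table CSV (units documented in a header comment)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing column(s) {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# angles in degrees; rate_spk_s in spikes/s\n")
        table[list(TRIAL_COLUMNS)].to_csv(fh, index=False)
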