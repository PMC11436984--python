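"""Delimited-text I/O for trial tables and flat configs.

Trial tables are plain CSV with a versioned schema marker on the first line
(``# schema=obslearn.trials.v1``).  Optional observation fields are written
as empty cells; unknown extra columns are preserved on read and write.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

SCHEMA_VERSION = "obslearn.trials.v1"

#: Required columns, in canonical order.
COLUMNS = [
    "subject",
    "site",
    "condition",
    "block",
    "stimulus_pair",
    "trial",
    "observation_absent",
    "outcome_visible",
    "dem_action",
    "dem_reward",
    "prediction",
    "choice",
    "observer_reward",
]

_INT_COLS = ["trial", "dem_action", "dem_reward", "prediction", "choice", "observer_reward"]
_BOOL_COLS = ["observation_absent", "outcome_visible"]


class SchemaError(ValueError):
    """Trial CSV does not match the expected schema."""


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as versioned CSV (missing fields → empty cells)."""
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table lacks required columns: {missing}")
    extra = [c for c in trials.columns if c not in COLUMNS]
    df = trials[COLUMNS + extra]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a versioned trial CSV, validating the schema marker and columns."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# schema={SCHEMA_VERSION}":
            raise SchemaError(
                f"{path}: expected schema marker '# schema={SCHEMA_VERSION}', got {first!r}"
            )
        df = pd.read_csv(fh)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: table contains no trials")
    for c in _INT_COLS:
        df[c] = df[c].astype("Int64")
    for c in _BOOL_COLS:
        df[c] = df[c].astype(bool)
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
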