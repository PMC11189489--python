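"""CSV schemas, validated readers/writers and run-config handling.

All tabular interchange uses plain CSV with unit-suffixed headers:

* biopsy:   ``animal_id, time_h, fl_signal, payload_signal, extract_signal``
            (plus ``true_recovery`` in debug output)
* tumor:    ``animal_id, group, day, volume_mm3`` (long format)
* survival: ``animal_id, group, time_days, event``

Readers are header-driven (column order is irrelevant), reject malformed rows
with line-numbered warnings, and fail loudly on missing columns or empty
results.  Durations are stored as collected — hours for biopsies, days for
tumor volumes — and converted internally.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .biopsy import BiopsyRecord, frame_to_records, records_to_frame
from .errors import SchemaError
from .growth import TumorTrajectory, frame_to_trajectories, trajectories_to_frame

__all__ = [
    "BIOPSY_COLUMNS",
    "TUMOR_COLUMNS",
    "read_biopsy_csv",
    "write_biopsy_csv",
    "read_tumor_csv",
    "write_tumor_csv",
    "write_survival_csv",
    "load_config",
    "write_run_record",
]

logger = logging.getLogger(__name__)

BIOPSY_COLUMNS = ("animal_id", "time_h", "fl_signal", "payload_signal", "extract_signal")
TUMOR_COLUMNS = ("animal_id", "group", "day", "volume_mm3")
SIGNAL_COLUMNS = ("fl_signal", "payload_signal", "extract_signal")


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_biopsy_csv(path: Union[str, Path]) -> list[BiopsyRecord]:
    """Read and validate a biopsy CSV into records.

    Rows with non-numeric or negative signals, or negative/missing times, are
    rejected with a line-numbered warning.  An empty validated result is an
    error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, BIOPSY_COLUMNS, path)

    numeric = df[list(BIOPSY_COLUMNS[1:])].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    bad |= numeric["time_h"] < 0
    for col in SIGNAL_COLUMNS:
        bad |= numeric[col] < 0
    if bad.any():
        for idx in df.index[bad]:
            # +2: header line plus 1-based numbering
            logger.warning("%s line %d: malformed row rejected", path, idx + 2)
    clean = df.loc[~bad].copy()
    clean[list(BIOPSY_COLUMNS[1:])] = numeric.loc[~bad]
    if clean.empty:
        raise SchemaError(f"{path}: no valid biopsy rows")
    return frame_to_records(clean)


def write_biopsy_csv(
    records: Union[Sequence[BiopsyRecord], pd.DataFrame],
    path: Union[str, Path],
    debug: bool = False,
) -> None:
    """Write records with the canonical schema; ``debug`` keeps ``true_recovery``."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records), debug=debug)
    if not debug and "true_recovery" in df.columns:
        df = df.drop(columns=["true_recovery"])
    df.to_csv(path, index=False)


def read_tumor_csv(path: Union[str, Path]) -> list[TumorTrajectory]:
    """Read and validate a tumor-volume CSV into per-animal trajectories.

    Days are sorted on load; duplicate (animal, day) measurements are a schema
    error; rows with non-positive volumes are rejected with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TUMOR_COLUMNS, path)
    numeric = df[["day", "volume_mm3"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | (numeric["volume_mm3"] <= 0) | (numeric["day"] < 0)
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("%s line %d: malformed row rejected", path, idx + 2)
    clean = df.loc[~bad].copy()
    clean[["day", "volume_mm3"]] = numeric.loc[~bad]
    if clean.empty:
        raise SchemaError(f"{path}: no valid tumor rows")
    dupes = clean.duplicated(subset=["animal_id", "day"], keep=False)
    if dupes.any():
        pairs = clean.loc[dupes, ["animal_id", "day"]].drop_duplicates()
        raise SchemaError(
            f"{path}: duplicate (animal_id, day) measurements: "
            + ", ".join(f"({a}, {d:g})" for a, d in pairs.itertuples(index=False))
        )
    return frame_to_trajectories(clean)


def write_tumor_csv(
    trajectories: Union[Sequence[TumorTrajectory], pd.DataFrame],
    path: Union[str, Path],
) -> None:
    df = (
        trajectories
        if isinstance(trajectories, pd.DataFrame)
        else trajectories_to_frame(list(trajectories))
    )
    df.to_csv(path, index=False)


def write_survival_csv(survival: pd.DataFrame, path: Union[str, Path]) -> None:
    cols = [c for c in ("animal_id", "group", "time_days", "event") if c in survival.columns]
    survival[cols].to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML (or JSON) run configuration."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def write_run_record(path: Union[str, Path], **resolved) -> None:
    """Record the fully resolved parameters (incl. seed) beside an output.

    Any stochastic run's outputs can be regenerated from this record.
    """
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        return str(obj)

    Path(path).write_text(json.dumps(resolved, indent=2, default=_default, sort_keys=True))
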