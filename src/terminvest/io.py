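"""CSV interchange for growth curves, cytometry events and doubling times.

All files are UTF-8 comma-separated tables with a header row and ``.`` as
the decimal separator.  Doubling-time tables use the column names
``Day, Phages, dt`` of the deposited-data convention (day of measure,
experimental treatment, doubling time in hours).  Truth tables ride along
as sidecar files with a ``_truth`` suffix.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import MalformedTableError

GROWTH_COLUMNS = ["well", "day", "treatment", "replicate", "time_h", "od650"]
CYTOMETRY_COLUMNS = ["day", "treatment", "event", "fsc", "ssc"]
DT_COLUMNS = ["Day", "Phages", "dt"]


def _read(path, required: list[str], label: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise MalformedTableError(f"{label} file {path}: missing columns {missing}")
    return table


def read_growth_csv(path) -> pd.DataFrame:
    return _read(path, GROWTH_COLUMNS, "growth")


def write_growth_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, columns=GROWTH_COLUMNS)
    return path


def read_cytometry_csv(path) -> pd.DataFrame:
    return _read(path, CYTOMETRY_COLUMNS, "cytometry")


def write_cytometry_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, columns=CYTOMETRY_COLUMNS)
    return path


def read_dt_csv(path) -> pd.DataFrame:
    return _read(path, DT_COLUMNS, "doubling-time")


def write_dt_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, columns=DT_COLUMNS)
    return path


def truth_sidecar_path(data_path) -> Path:
    """Path of the ``_truth`` sidecar next to a generated data file."""
    data_path = Path(data_path)
    return data_path.with_name(data_path.stem + "_truth" + data_path.suffix)
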