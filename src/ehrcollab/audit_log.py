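"""Domain model and delimited-text I/O for EHR audit-log data.

An audit-log *event* is one row: an HCW (health-care worker) performed an
action on one patient's record at a point in time, at second resolution.
Events, intervals, visit metadata and HCW metadata all live in pandas
DataFrames with fixed column schemas; the functions here read and write the
delimited-text representations the rest of the pipeline consumes and emits.

Timestamps are treated as naive local time: the source logs carry no zone,
so daylight-saving transitions may create apparent gaps or overlaps and are
not corrected. Duplicate rows (identical on all four fields) are kept —
repeated identical actions are legitimate audit events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ("hcw_id", "patient_id", "action_id", "timestamp")

#: Default timestamp pattern of raw log exports, e.g. "4/5/2020 2:14:25".
DEFAULT_TIMESTAMP_FORMAT = "%m/%d/%Y %H:%M:%S"

#: The eight role categories HCW specialties collapse into, plus "unknown".
ROLES = (
    "neonatologist",
    "fellow",
    "frontline provider",
    "nurse",
    "respiratory therapist",
    "consultant",
    "ancillary staff",
    "support staff",
)
UNKNOWN_ROLE = "unknown"


class AuditLogError(ValueError):
    """Raised for unusable audit-log input (missing file, wrong schema, ...)."""


@dataclass(frozen=True)
class LoadReport:
    """Row accounting for one :func:`read_events` call."""

    rows_read: int
    rows_kept: int
    rows_dropped: int


def read_events(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    timestamp_format: str | None = DEFAULT_TIMESTAMP_FORMAT,
    delimiter: str = ",",
) -> tuple[pd.DataFrame, LoadReport]:
    """Read an event table, dropping malformed rows.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Mapping from canonical names (``hcw_id``, ``patient_id``,
        ``action_id``, ``timestamp``) to the column names used in the file.
        Identity by default.
    timestamp_format:
        strftime pattern for the timestamp column; ``None`` lets pandas
        infer (useful for ISO output written by :func:`write_events`).
    delimiter:
        Field separator (``","`` or ``"\\t"``).

    Returns
    -------
    events, report:
        Events sorted by ``(hcw_id, patient_id, timestamp)`` with a stable
        sort (equal timestamps keep file order), and the row accounting.
        Rows with unparseable timestamps or missing identifiers are dropped
        and counted.

    Raises
    ------
    AuditLogError
        If the file is missing, mapped columns are absent, or more than half
        of the rows are dropped (a symptom of a wrong ``timestamp_format``).
    """
    path = Path(path)
    if not path.exists():
        raise AuditLogError(f"event file not found: {path}")
    column_map = column_map or {}
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    rename = {column_map.get(c, c): c for c in EVENT_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise AuditLogError(f"missing columns in {path}: {missing}")
    df = raw.rename(columns=rename)[list(EVENT_COLUMNS)].copy()

    rows_read = len(df)
    df["timestamp"] = pd.to_datetime(
        df["timestamp"], format=timestamp_format, errors="coerce"
    )
    ok = (
        df["timestamp"].notna()
        & df["hcw_id"].notna()
        & df["patient_id"].notna()
        & df["action_id"].notna()
        & (df["action_id"].astype(str).str.len() > 0)
    )
    df = df[ok]
    rows_kept = len(df)
    report = LoadReport(rows_read, rows_kept, rows_read - rows_kept)
    if rows_read > 0 and report.rows_dropped > rows_read / 2:
        raise AuditLogError(
            f"{report.rows_dropped}/{rows_read} rows dropped while reading "
            f"{path}; check timestamp_format (current: {timestamp_format!r})"
        )
    df = sort_events(df)
    return df, report


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by ``(hcw_id, patient_id, timestamp)``; resets the index."""
    return events.sort_values(
        ["hcw_id", "patient_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)


def events_from_records(records: list[tuple]) -> pd.DataFrame:
    """Build a sorted event frame from ``(hcw, patient, action, ts)`` tuples."""
    df = pd.DataFrame(records, columns=list(EVENT_COLUMNS))
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return sort_events(df)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular artifact as headered CSV.

    String and integer fields round-trip bit-identically through the
    corresponding reader. An empty frame yields a header-only file.
    """
    if records is None:
        raise AuditLogError("records must not be None")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write events as CSV with ISO timestamps (read back with
    ``timestamp_format=None``)."""
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    write_table(out, path)


def read_hcw_meta(path: str | Path) -> pd.DataFrame:
    """Read HCW metadata (``hcw_id``, ``specialty``, ``role``).

    Unrecognized roles are coerced to ``"unknown"``; each ``hcw_id`` must map
    to a single specialty/role row.
    """
    meta = pd.read_csv(path, dtype=str)
    for col in ("hcw_id", "specialty", "role"):
        if col not in meta.columns:
            raise AuditLogError(f"hcw metadata missing column {col!r}")
    if meta["hcw_id"].duplicated().any():
        raise AuditLogError("duplicate hcw_id rows in HCW metadata")
    meta["role"] = meta["role"].where(meta["role"].isin(ROLES), UNKNOWN_ROLE)
    return meta.reset_index(drop=True)


def read_visits(path: str | Path, timestamp_format: str | None = None) -> pd.DataFrame:
    """Read visit metadata (``patient_id``, ``admission``, ``discharge``)."""
    visits = pd.read_csv(path, dtype=str)
    for col in ("patient_id", "admission", "discharge"):
        if col not in visits.columns:
            raise AuditLogError(f"visit metadata missing column {col!r}")
    for col in ("admission", "discharge"):
        visits[col] = pd.to_datetime(visits[col], format=timestamp_format)
    if (visits["admission"] >= visits["discharge"]).any():
        raise AuditLogError("visit with admission >= discharge")
    return visits.reset_index(drop=True)


_ACTION_SEP = "|"


def write_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write an interval table; the ``actions`` multiset column (tuples) is
    serialized pipe-joined."""
    out = intervals.copy()
    if "actions" in out.columns:
        out["actions"] = out["actions"].map(
            lambda a: _ACTION_SEP.join(a) if isinstance(a, (tuple, list)) else a
        )
    for col in ("start", "stop"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    write_table(out, path)


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read an interval table written by :func:`write_intervals`."""
    df = pd.read_csv(path, dtype={"hcw_id": str, "patient_id": str})
    for col in ("start", "stop"):
        df[col] = pd.to_datetime(df[col])
    if "actions" in df.columns:
        df["actions"] = df["actions"].map(
            lambda s: tuple(s.split(_ACTION_SEP)) if isinstance(s, str) else ()
        )
    return df
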