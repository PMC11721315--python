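"""Reading, validating and writing breath-by-breath ventilator logs.

A breath log is held in memory as a :class:`pandas.DataFrame` with one row
per breath and the canonical columns

========== =====================================================
``time``       seconds since the cohort epoch (float, strictly increasing)
``spo2``       pulse-oximetry saturation, percent in [50, 100]; NaN = missing
``peep``       measured PEEP, cm H2O in [0, 30]
``fio2``       inspired-oxygen fraction, percent in [21, 100]
``mode``       ``automated`` | ``conventional_pc`` | ``conventional_ps``
``controller`` automation controller status: ``automated`` | ``manual`` | ``frozen``
``alarm``      bool, oxygenation-related ventilator alarm active
``set_peep``   operator/controller set PEEP, cm H2O
``set_fio2``   operator/controller set FiO2, percent
========== =====================================================

Vendor exports with different column names are mapped via a config-driven
schema (``schema={"time": "Timestamp", ...}``).  Timestamps may be ISO-8601
datetimes or plain numeric seconds; both are normalised to float seconds.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: canonical column order, also the default CSV header
CANONICAL_COLUMNS = (
    "time", "spo2", "peep", "fio2",
    "mode", "controller", "alarm", "set_peep", "set_fio2",
)

NUMERIC_COLUMNS = ("time", "spo2", "peep", "fio2", "set_peep", "set_fio2")

MODES = ("automated", "conventional_pc", "conventional_ps")
CONTROLLER_STATUSES = ("automated", "manual", "frozen")

#: tokens treated as a missing value (case-insensitive); empty cell too
MISSING_TOKENS = frozenset({"", "na", "nan"})

_TRUE_TOKENS = frozenset({"1", "true", "t", "yes"})
_FALSE_TOKENS = frozenset({"0", "false", "f", "no", "", "na", "nan"})


@dataclasses.dataclass
class ParseReport:
    """Bookkeeping for one :func:`read_breath_log` call.

    Conservation invariant: ``rows_read == rows_kept + rows_dropped``.
    """

    rows_read: int = 0
    rows_kept: int = 0
    rows_dropped: int = 0
    missing_counts: dict[str, int] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class PatientManifest:
    """Phase windows for one patient of the crossover design.

    The nominal design is two 3 h phases separated by a 30 min washout, but
    arbitrary positive durations are accepted.  The washout interval is
    implied: ``[phase1_end, phase2_start)``.
    """

    patient_id: str
    first_mode: str  # "automated" | "conventional"
    phase1_start: float
    phase1_end: float
    phase2_start: float
    phase2_end: float

    def __post_init__(self) -> None:
        if self.first_mode not in ("automated", "conventional"):
            raise ValidationError(
                f"manifest {self.patient_id}: first_mode must be "
                f"'automated' or 'conventional', got {self.first_mode!r}")
        if not (self.phase1_start < self.phase1_end):
            raise ValidationError(
                f"manifest {self.patient_id}: phase 1 duration must be > 0")
        if not (self.phase2_start < self.phase2_end):
            raise ValidationError(
                f"manifest {self.patient_id}: phase 2 duration must be > 0")
        if self.phase1_end > self.phase2_start:
            raise ValidationError(
                f"manifest {self.patient_id}: phase 1 overlaps phase 2 "
                f"(phase1_end={self.phase1_end} > phase2_start={self.phase2_start})")

    @property
    def phase_mode(self) -> dict[str, str]:
        """Map phase slot -> arm label."""
        second = "conventional" if self.first_mode == "automated" else "automated"
        return {"phase1": self.first_mode, "phase2": second}


def _parse_time_column(raw: pd.Series) -> pd.Series:
    """Accept numeric seconds or ISO-8601 datetimes; return float seconds."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    # fall back to datetime parsing for the whole column
    stamps = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if stamps.notna().all():
        # Unix epoch keeps all logs of a cohort on one common time axis.
        return stamps.astype("int64").astype(float) / 1e9
    bad = raw[numeric.isna() & stamps.isna()]
    raise ValidationError(
        f"unparseable timestamp {bad.iloc[0]!r} at row {bad.index[0]}")


def read_breath_log(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a breath-by-breath CSV into the canonical frame.

    Parameters
    ----------
    path
        CSV file with a header row, comma delimiter, ``.`` decimal separator.
    schema
        Optional mapping from canonical column name to the column name used
        in the file, e.g. ``{"time": "Date_Time", "spo2": "SpO2 [%]"}``.
        Unmapped canonical names are looked up verbatim.

    Returns
    -------
    (frame, report)
        ``frame`` has the canonical columns, sorted by time.  ``report``
        counts rows read/kept/dropped and missing values per column.

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    ValidationError
        If timestamps are not strictly increasing, or a value is out of its
        physical range.
    """
    path = Path(path)
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)

    report = ParseReport(rows_read=len(raw))
    cols: dict[str, pd.Series] = {}
    for canon in CANONICAL_COLUMNS:
        name = schema.get(canon, canon)
        if name not in raw.columns:
            raise ConfigurationError(
                f"{path.name}: required column {name!r} (for {canon!r}) not found; "
                f"available: {list(raw.columns)}")
        cols[canon] = raw[name]

    frame = pd.DataFrame(index=raw.index)
    drop_mask = np.zeros(len(raw), dtype=bool)

    frame["time"] = _parse_time_column(cols["time"])

    for canon in ("spo2", "peep", "fio2", "set_peep", "set_fio2"):
        tokens = cols[canon].str.strip()
        is_missing = tokens.str.lower().isin(MISSING_TOKENS)
        numeric = pd.to_numeric(tokens, errors="coerce")
        malformed = numeric.isna() & ~is_missing
        if malformed.any():
            n = int(malformed.sum())
            report.warnings.append(
                f"column {canon!r}: {n} unrecognised token(s), rows dropped "
                f"(first: {tokens[malformed].iloc[0]!r})")
            drop_mask |= malformed.to_numpy()
        report.missing_counts[canon] = int(is_missing.sum())
        frame[canon] = numeric.astype(float)

    for canon, allowed in (("mode", MODES), ("controller", CONTROLLER_STATUSES)):
        tokens = cols[canon].str.strip().str.lower()
        bad = ~tokens.isin(allowed)
        if bad.any():
            report.warnings.append(
                f"column {canon!r}: {int(bad.sum())} unknown value(s), rows dropped "
                f"(first: {tokens[bad].iloc[0]!r})")
            drop_mask |= bad.to_numpy()
        frame[canon] = tokens

    alarm_tokens = cols["alarm"].str.strip().str.lower()
    bad_alarm = ~alarm_tokens.isin(_TRUE_TOKENS | _FALSE_TOKENS)
    if bad_alarm.any():
        report.warnings.append(
            f"column 'alarm': {int(bad_alarm.sum())} unrecognised flag(s), rows dropped")
        drop_mask |= bad_alarm.to_numpy()
    frame["alarm"] = alarm_tokens.isin(_TRUE_TOKENS)

    frame = frame.loc[~drop_mask, list(CANONICAL_COLUMNS)].reset_index(drop=True)
    report.rows_dropped = int(drop_mask.sum())
    report.rows_kept = len(frame)

    validate_breath_frame(frame)
    return frame, report


def validate_breath_frame(frame: pd.DataFrame) -> None:
    """Enforce the breath-record invariants; raise ValidationError on breach."""
    t = frame["time"].to_numpy(float)
    if len(t) > 1:
        diffs = np.diff(t)
        if not (diffs > 0).all():
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(
                f"timestamps not strictly increasing at row {row} "
                f"(t={t[row]} after t={t[row - 1]})")
    checks = (
        ("spo2", 50.0, 100.0),
        ("peep", 0.0, 30.0),
        ("fio2", 21.0, 100.0),
        ("set_peep", 0.0, 30.0),
        ("set_fio2", 21.0, 100.0),
    )
    for col, lo, hi in checks:
        v = frame[col].to_numpy(float)
        bad = ~np.isnan(v) & ((v < lo) | (v > hi))
        if bad.any():
            row = int(np.argmax(bad))
            raise ValidationError(
                f"column {col!r} out of range [{lo}, {hi}] at row {row} "
                f"(value {v[row]})")
    conventional = frame["mode"].isin(("conventional_pc", "conventional_ps"))
    if (conventional & (frame["controller"] != "manual")).any():
        row = int(np.argmax((conventional & (frame["controller"] != "manual")).to_numpy()))
        raise ValidationError(
            f"controller status must be 'manual' under a conventional mode (row {row})")


def write_breath_log(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical breath frame to CSV; round-trips with read_breath_log.

    Missing numeric values are written as empty cells; the alarm flag as 0/1.
    Floats are written with enough digits to round-trip (``%.10g``).
    """
    out = frame.loc[:, list(CANONICAL_COLUMNS)].copy()
    out["alarm"] = out["alarm"].astype(int)
    out.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_manifest(path: str | Path) -> list[PatientManifest]:
    """Read the patient manifest CSV (one row per patient)."""
    raw = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "first_mode", "phase1_start",
                "phase1_end", "phase2_start", "phase2_end"]
    for col in required:
        if col not in raw.columns:
            raise ConfigurationError(f"manifest missing column {col!r}")
    return [
        PatientManifest(
            patient_id=str(r.patient_id),
            first_mode=str(r.first_mode),
            phase1_start=float(r.phase1_start),
            phase1_end=float(r.phase1_end),
            phase2_start=float(r.phase2_start),
            phase2_end=float(r.phase2_end),
        )
        for r in raw.itertuples(index=False)
    ]


def write_manifest(manifests: Sequence[PatientManifest], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in manifests]).to_csv(
        path, index=False, float_format="%.10g")
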