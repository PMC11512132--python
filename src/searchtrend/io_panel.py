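"""Reading, validating and writing daily search-volume panels.

A *panel* is a collection of daily relative search-volume series, one per
age group, on the 0-100 export scale used by search-trend services (the
period maximum for each group is scaled to 100).  The on-disk dialect is a
plain CSV with a ``date`` column (ISO ``YYYY-MM-DD``) followed by one
numeric column per group, e.g.::

    date,13-18,19-59
    2016-01-01,12.34,45.67
    2016-01-02,11.00,44.10

The reader enforces a strict daily calendar: every day between the minimum
and maximum date must appear exactly once.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PanelError",
    "CalendarError",
    "ParseError",
    "AlignmentError",
    "ScaleWarning",
    "RawDailySeries",
    "Panel",
    "read_panel_csv",
    "write_panel_csv",
    "read_table_csv",
    "write_table_csv",
]

DATE_COLUMN = "date"
DATE_FORMAT = "%Y-%m-%d"
#: Export convention: the period maximum of each group should be this value.
EXPORT_MAX = 100.0
_FLOAT_FORMAT = "%.12g"  # round-trips 0-100 values to well below 1e-9


class PanelError(ValueError):
    """Base class for panel validation failures."""


class CalendarError(PanelError):
    """The date sequence is not the exact contiguous daily calendar."""


class ParseError(PanelError):
    """A cell could not be parsed or is out of the 0-100 export range."""


class AlignmentError(PanelError):
    """Member series of a panel do not share one date range."""


class ScaleWarning(UserWarning):
    """A group's maximum deviates from the export convention (max = 100)."""


@dataclasses.dataclass(frozen=True)
class RawDailySeries:
    """One group's daily relative search volume on the 0-100 export scale.

    Parameters
    ----------
    group_label
        Group identifier, e.g. ``"13-18"`` or ``"19-59"``.
    start_date
        Calendar date of the first value.
    values
        One value per day, contiguous; each finite and in ``[0, 100]``.
    """

    group_label: str
    start_date: dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise PanelError(f"{self.group_label!r}: values must be a nonempty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise ParseError(f"{self.group_label!r}: non-finite value present")
        if v.min() < 0.0 or v.max() > EXPORT_MAX + 1e-9:
            raise ParseError(
                f"{self.group_label!r}: values outside the 0-{EXPORT_MAX:g} export scale"
            )

    @property
    def n_days(self) -> int:
        return int(self.values.size)

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.n_days - 1)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


@dataclasses.dataclass(frozen=True)
class Panel:
    """A set of :class:`RawDailySeries` sharing one date range."""

    series_by_group: Mapping[str, RawDailySeries]

    def __post_init__(self) -> None:
        if not self.series_by_group:
            raise PanelError("panel must contain at least one group")
        ranges = {
            (s.start_date, s.end_date) for s in self.series_by_group.values()
        }
        if len(ranges) != 1:
            raise AlignmentError(f"member series have mismatched date ranges: {sorted(ranges)}")
        for label, s in self.series_by_group.items():
            if label != s.group_label:
                raise AlignmentError(f"key {label!r} does not match series label {s.group_label!r}")

    @property
    def period(self) -> tuple[dt.date, dt.date]:
        s = next(iter(self.series_by_group.values()))
        return (s.start_date, s.end_date)

    @property
    def groups(self) -> list[str]:
        return list(self.series_by_group)

    def to_frame(self) -> pd.DataFrame:
        """Panel as a date-indexed DataFrame, one column per group."""
        s = next(iter(self.series_by_group.values()))
        return pd.DataFrame(
            {label: ser.values for label, ser in self.series_by_group.items()},
            index=s.dates,
        )


def _check_contiguous_calendar(dates: pd.DatetimeIndex) -> None:
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise CalendarError(f"duplicate date {dup.date().isoformat()}")
    expected = pd.date_range(dates.min(), dates.max(), freq="D")
    missing = expected.difference(dates)
    if len(missing) > 0:
        raise CalendarError(
            f"missing date {missing[0].date().isoformat()} "
            f"({len(missing)} day(s) absent from the daily calendar)"
        )


def _parse_frame(path: str | Path) -> pd.DataFrame:
    """Shared CSV parsing: date column + numeric group columns, strict calendar."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in raw.columns]
    raw.columns = cols
    if not cols or cols[0].lower() != DATE_COLUMN:
        raise ParseError(f"{path}: first column must be {DATE_COLUMN!r}, got {cols[:1]}")
    if len(cols) < 2:
        raise ParseError(f"{path}: no group columns found")
    dates = pd.to_datetime(raw[cols[0]], format=DATE_FORMAT, errors="coerce")
    if dates.isna().any():
        row = int(dates.isna().idxmax()) + 2  # header is row 1
        raise ParseError(f"{path}: unparseable date at row {row}")
    frame = pd.DataFrame(index=pd.DatetimeIndex(dates.values))
    for col in cols[1:]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
        frame[col] = vals.to_numpy(dtype=float)
    _check_contiguous_calendar(frame.index)
    return frame.sort_index()


def read_panel_csv(path: str | Path) -> Panel:
    """Read a 0-100 scale daily panel, validating calendar and value range.

    Raises
    ------
    CalendarError
        If a day is missing or duplicated, naming the offending date.
    ParseError
        If a cell is non-numeric or outside the 0-100 export scale,
        naming the row.
    """
    frame = _parse_frame(path)
    series = {}
    for col in frame.columns:
        v = frame[col].to_numpy()
        bad = np.nonzero((v < 0.0) | (v > EXPORT_MAX + 1e-9))[0]
        if bad.size:
            raise ParseError(
                f"{path}: value {v[bad[0]]!r} in column {col!r} at row {int(bad[0]) + 2} "
                f"is outside the 0-{EXPORT_MAX:g} export scale"
            )
        if abs(v.max() - EXPORT_MAX) > 0.5:
            warnings.warn(
                f"group {col!r}: maximum {v.max():g} != {EXPORT_MAX:g}; "
                "this looks like a truncated subset of an export",
                ScaleWarning,
                stacklevel=2,
            )
        series[col] = RawDailySeries(
            group_label=col, start_date=frame.index[0].date(), values=v
        )
    return Panel(series_by_group=series)


def write_panel_csv(panel: Panel, path: str | Path) -> None:
    """Write a panel in the CSV dialect read by :func:`read_panel_csv`.

    Round-trips values to an absolute difference below 1e-9.
    """
    if not isinstance(panel, Panel) or not panel.series_by_group:
        raise PanelError("write_panel_csv requires a non-empty Panel")
    write_table_csv(panel.to_frame(), path)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    """Read a date-indexed daily value table (same dialect, no 0-100 bound).

    Used for intermediate pipeline products (normalized, slow and fast
    series), where values are unitless ratios rather than export-scale
    volumes.
    """
    return _parse_frame(path)


def write_table_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a date-indexed daily value table in the panel CSV dialect."""
    out = frame.copy()
    out.index = out.index.strftime(DATE_FORMAT)
    out.index.name = DATE_COLUMN
    out.to_csv(Path(path), float_format=_FLOAT_FORMAT)
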