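"""Event-level diagnosis data -> code x month unique-patient count matrices.

The unit of analysis throughout the package is the number of *distinct*
patients receiving a diagnosis code in a calendar month.  Codes are opaque
labels (ICD-9 in practice, but nothing here parses them); dates are calendar
dates with no time-zone handling.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosisEvent",
    "MonthlyCounts",
    "read_events",
    "events_frame",
    "aggregate_monthly",
    "filter_codes",
    "restrict_period",
]

EVENT_COLUMNS = ("patient_id", "code", "date")


@dataclass(frozen=True)
class DiagnosisEvent:
    """One patient/code/date record, the atomic input."""

    patient_id: str
    code: str
    date: str  # ISO-8601 calendar date

    def __post_init__(self) -> None:
        if not str(self.code):
            raise ValueError("code must be non-empty")
        pd.Timestamp(self.date)  # raises on unparseable date


def events_frame(events: Iterable[DiagnosisEvent] | pd.DataFrame) -> pd.DataFrame:
    """Coerce an event iterable (or frame) to the canonical event frame."""
    if isinstance(events, pd.DataFrame):
        missing = set(EVENT_COLUMNS) - set(events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        return events.loc[:, list(EVENT_COLUMNS)].copy()
    return pd.DataFrame(
        [(e.patient_id, e.code, e.date) for e in events], columns=list(EVENT_COLUMNS)
    )


def read_events(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited event table with a patient_id/code/date header."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    return events_frame(frame)


class MonthlyCounts:
    """Code x month matrix of unique-patient counts on a contiguous month axis.

    Parameters
    ----------
    frame
        Integer matrix with codes as the index and a monthly
        :class:`pandas.PeriodIndex` as columns.  Months must be contiguous
        and strictly increasing.
    """

    def __init__(self, frame: pd.DataFrame):
        cols = frame.columns
        if not isinstance(cols, pd.PeriodIndex):
            cols = pd.PeriodIndex(pd.to_datetime(list(cols)), freq="M")
            frame = frame.set_axis(cols, axis=1)
        if len(cols) == 0:
            warnings.warn("empty month axis", stacklevel=2)
        elif not (np.diff(cols.asi8) == 1).all():
            raise ValueError("months must be contiguous and strictly increasing")
        values = frame.to_numpy()
        if len(values) and (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.frame = frame.astype(np.int64)

    # -- accessors -----------------------------------------------------
    @property
    def codes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def months(self) -> pd.PeriodIndex:
        return self.frame.columns

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def time_axis(self) -> np.ndarray:
        """Decimal years at mid-month (Jan 1997 -> 1997.0417), evenly spaced."""
        m = self.months
        return np.asarray(m.year + (m.month - 0.5) / 12.0, dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, MonthlyCounts) and self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return f"MonthlyCounts({len(self.codes)} codes x {len(self.months)} months)"

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path, header_comment: str | None = None) -> None:
        out = self.frame.copy()
        out.columns = [str(p) for p in self.months]
        out.index.name = "code"
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "MonthlyCounts":
        frame = pd.read_csv(path, comment="#", index_col="code")
        return cls(frame)


def _parse_dates(events: pd.DataFrame) -> pd.Series:
    dates = pd.to_datetime(events["date"], errors="coerce", format="mixed")
    bad = dates.isna() & events["date"].notna()
    if bad.any():
        rows = list(events.index[bad][:20])
        raise ValueError(f"unparseable dates at rows {rows}")
    if dates.isna().any():
        rows = list(events.index[dates.isna()][:20])
        raise ValueError(f"missing dates at rows {rows}")
    return dates


def aggregate_monthly(
    events: Iterable[DiagnosisEvent] | pd.DataFrame,
    start: str | pd.Period | None = None,
    end: str | pd.Period | None = None,
) -> MonthlyCounts:
    """Count distinct patients per (code, month).

    Cell (c, m) is the number of distinct patient identifiers with at least
    one event of code c in month m.  Events outside [start, end] are dropped;
    months in the range with no events appear as zero columns.
    """
    ev = events_frame(events)
    if ev.empty:
        warnings.warn("no events supplied; returning an empty matrix", stacklevel=2)
        return MonthlyCounts(pd.DataFrame(columns=pd.PeriodIndex([], freq="M")))
    months = _parse_dates(ev).dt.to_period("M")
    start = pd.Period(start, freq="M") if start is not None else months.min()
    end = pd.Period(end, freq="M") if end is not None else months.max()
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    keep = (months >= start) & (months <= end)
    ev = ev.loc[keep].assign(month=months[keep])
    if ev.empty:
        warnings.warn("no events in the requested window", stacklevel=2)
        return MonthlyCounts(pd.DataFrame(columns=pd.period_range(start, end, freq="M")))
    table = (
        ev.groupby(["code", "month"], observed=True)["patient_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    table = table.reindex(columns=pd.period_range(start, end, freq="M"), fill_value=0)
    table = table.sort_index()
    table.index = table.index.astype(str)
    return MonthlyCounts(table)


def filter_codes(counts: MonthlyCounts, min_cases: int = 500) -> MonthlyCounts:
    """Keep codes whose total count is strictly greater than ``min_cases``."""
    if min_cases < 0:
        raise ValueError("min_cases must be >= 0")
    totals = counts.frame.sum(axis=1)
    return MonthlyCounts(counts.frame.loc[totals > min_cases])


def restrict_period(
    counts: MonthlyCounts, start_year: int = 1997, end_year: int = 2009
) -> MonthlyCounts:
    """Limit columns to January ``start_year`` .. December ``end_year``."""
    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    lo = pd.Period(f"{start_year}-01", freq="M")
    hi = pd.Period(f"{end_year}-12", freq="M")
    keep = [m for m in counts.months if lo <= m <= hi]
    if not keep:
        raise ValueError(
            f"no months between {lo} and {hi} present in the data "
            f"({counts.months[0]}..{counts.months[-1]})"
        )
    return MonthlyCounts(counts.frame.loc[:, keep])
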