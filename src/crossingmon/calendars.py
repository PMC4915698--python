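"""Monitoring-year calendar.

A *monitoring year* runs from April 1 of one calendar year through March 31
of the next (inclusive on both ends), aligned with the hunting/breeding
season, and is labelled ``"YYYY/YYYY+1"``.  Every timestamp maps to exactly
one monitoring year, so a span of consecutive monitoring years tiles time
without gaps or overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time

__all__ = [
    "MonitoringYear",
    "MonitoringCalendar",
    "CalendarRangeError",
    "monitoring_year_label",
    "monitoring_year_of",
]


class CalendarRangeError(ValueError):
    """Raised when a timestamp falls outside the configured calendar span."""


def _start_year_of(ts: datetime | date) -> int:
    return ts.year if ts.month >= 4 else ts.year - 1


def monitoring_year_label(ts: datetime | date) -> str:
    """Label of the monitoring year containing ``ts`` (no range check)."""
    y = _start_year_of(ts)
    return f"{y}/{y + 1}"


@dataclass(frozen=True)
class MonitoringYear:
    """One April-to-March monitoring year.

    Attributes
    ----------
    label : str
        ``"YYYY/YYYY+1"``.
    start : date
        April 1 of the first calendar year (inclusive).
    end : date
        March 31 of the second calendar year (inclusive).
    """

    label: str
    start: date
    end: date

    @classmethod
    def from_start_year(cls, year: int) -> "MonitoringYear":
        return cls(
            label=f"{year}/{year + 1}",
            start=date(year, 4, 1),
            end=date(year + 1, 3, 31),
        )

    @property
    def start_year(self) -> int:
        return self.start.year

    def contains(self, ts: datetime | date) -> bool:
        d = ts.date() if isinstance(ts, datetime) else ts
        return self.start <= d <= self.end

    @property
    def start_dt(self) -> datetime:
        return datetime.combine(self.start, time.min)

    @property
    def end_dt(self) -> datetime:
        return datetime.combine(self.end, time.max)


@dataclass(frozen=True)
class MonitoringCalendar:
    """A contiguous run of monitoring years.

    Parameters
    ----------
    first_start_year : int
        Calendar year whose April 1 opens the first monitoring year.
    n_years : int
        Number of consecutive monitoring years covered.
    """

    first_start_year: int
    n_years: int
    years: tuple[MonitoringYear, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("calendar must span at least one monitoring year")
        object.__setattr__(
            self,
            "years",
            tuple(
                MonitoringYear.from_start_year(self.first_start_year + i)
                for i in range(self.n_years)
            ),
        )

    @property
    def labels(self) -> list[str]:
        return [y.label for y in self.years]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def label_of(self, ts: datetime | date) -> str:
        """Monitoring-year label for ``ts``; raises if outside the span."""
        y = _start_year_of(ts)
        if not (self.first_start_year <= y < self.first_start_year + self.n_years):
            raise CalendarRangeError(
                f"timestamp {ts} falls outside the monitoring calendar "
                f"{self.labels[0]} .. {self.labels[-1]}"
            )
        return f"{y}/{y + 1}"

    def year(self, label: str) -> MonitoringYear:
        for y in self.years:
            if y.label == label:
                return y
        raise KeyError(label)

    def span_labels(self, first_label: str, last_label: str) -> list[str]:
        """All labels from ``first_label`` through ``last_label`` inclusive."""
        labels = self.labels
        i, j = labels.index(first_label), labels.index(last_label)
        if j < i:
            raise ValueError(f"year span reversed: {first_label} .. {last_label}")
        return labels[i : j + 1]


def monitoring_year_of(
    ts: datetime | date, calendar: MonitoringCalendar | None = None
) -> str:
    """Map a timestamp to its monitoring-year label.

    With a calendar the timestamp must fall inside the configured span
    (:class:`CalendarRangeError` otherwise); without one the label is
    computed unconditionally.
    """
    if calendar is not None:
        return calendar.label_of(ts)
    return monitoring_year_label(ts)
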