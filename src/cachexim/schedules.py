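"""Dosing schedules as explicit event lists.

A schedule is a finite, time-sorted sequence of bolus dosing events
(time in days since treatment start, dose in mg/kg).  Builders cover the
standard regimen families used for 5-FU in mice: daily, k-on/j-off cycles,
arbitrary weekly on/off patterns, every-other-day, and metronomic
(multiple equal doses per day at a fixed weekly total).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseEvent",
    "Schedule",
    "make_daily",
    "make_cycle",
    "make_weekly_pattern",
    "make_every_other_day",
    "make_metronomic",
    "weekly_total",
    "parse_schedule",
]


@dataclass(frozen=True)
class DoseEvent:
    """A single bolus dose: ``time`` days after treatment start, ``amount`` mg/kg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")


@dataclass(frozen=True)
class Schedule:
    """An ordered dosing schedule.

    Events are sorted by strictly increasing time; two boluses can never
    share an administration time (they would be a single larger bolus).
    """

    label: str
    events: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule events must be sorted by strictly increasing time")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([e.amount for e in self.events], dtype=float)

    @property
    def end(self) -> float:
        """Time of the last dose (0.0 for an empty schedule)."""
        return self.events[-1].time if self.events else 0.0

    @property
    def total_dose(self) -> float:
        return float(sum(e.amount for e in self.events))

    def empty(self) -> "Schedule":
        """The matching zero-dose (control) schedule."""
        return Schedule(label=f"control({self.label})", events=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.times, "dose_mg_per_kg": self.amounts}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "from_csv") -> "Schedule":
        events = tuple(
            DoseEvent(float(t), float(d))
            for t, d in zip(frame["time_days"], frame["dose_mg_per_kg"])
        )
        return cls(label=label, events=events)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "Schedule":
        return cls.from_frame(pd.read_csv(path), label=label or str(path))


def _events(times, dose: float) -> tuple[DoseEvent, ...]:
    return tuple(DoseEvent(float(t), float(dose)) for t in times)


def make_daily(dose: float, n_days: int = 28, label: str | None = None) -> Schedule:
    """One ``dose`` mg/kg bolus on each of days 0 .. n_days-1."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    return Schedule(label or f"daily:{dose:g}", _events(range(n_days), dose))


def make_cycle(
    on_days: int, off_days: int, dose: float, horizon: int = 28, label: str | None = None
) -> Schedule:
    """Repeating blocks of ``on_days`` dosed days then ``off_days`` holidays.

    Daily events within on-blocks, truncated at ``horizon`` days; e.g. the
    classic 5-on/2-off week-day schedule is ``make_cycle(5, 2, dose)``.
    """
    if on_days < 1:
        raise ValueError("on_days must be at least 1")
    if off_days < 0:
        raise ValueError("off_days must be non-negative")
    if dose <= 0:
        raise ValueError("dose must be positive")
    if horizon < 1:
        raise ValueError("horizon must be at least 1 day")
    period = on_days + off_days
    days = [d for d in range(horizon) if d % period < on_days]
    return Schedule(label or f"{on_days}on{off_days}off:{dose:g}", _events(days, dose))


def make_weekly_pattern(
    pattern: tuple[int, ...], dose: float, n_weeks: int = 4, label: str | None = None
) -> Schedule:
    """Weekly on/off block pattern, starting with an on-block.

    ``pattern`` alternates on/off block lengths within one week, e.g.
    ``(4, 1, 1, 1)`` doses on weekly offsets {0, 1, 2, 3, 5}.  Block lengths
    must sum to at most 7; any remainder of the week is off.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if not pattern or any(b < 1 for b in pattern):
        raise ValueError("pattern blocks must be positive integers")
    if sum(pattern) > 7:
        raise ValueError(f"pattern blocks sum to {sum(pattern)} > 7 days")
    offsets = []
    day = 0
    for i, block in enumerate(pattern):
        if i % 2 == 0:  # on-block
            offsets.extend(range(day, day + block))
        day += block
    days = [7 * w + o for w in range(n_weeks) for o in offsets]
    name = label or "pattern:" + ",".join(str(b) for b in pattern) + f"@{dose:g}"
    return Schedule(name, _events(sorted(days), dose))


def make_every_other_day(dose: float, horizon: int = 28, label: str | None = None) -> Schedule:
    """Doses on days 0, 2, 4, ... below ``horizon``."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    return Schedule(label or f"eod:{dose:g}", _events(range(0, horizon, 2), dose))


def make_metronomic(
    doses_per_day: int, weekly_total: float, n_days: int = 28, label: str | None = None
) -> Schedule:
    """``doses_per_day`` equal doses per day, equally spaced, at a fixed weekly total.

    The per-dose amount is ``weekly_total / (7 * doses_per_day)`` and intraday
    times are the day's integer time plus k/doses_per_day day, k = 0 .. n-1.
    """
    if not 1 <= doses_per_day <= 6:
        raise ValueError("doses_per_day must be in 1..6")
    if weekly_total <= 0:
        raise ValueError("weekly_total must be positive")
    per_dose = weekly_total / (7 * doses_per_day)
    times = [d + k / doses_per_day for d in range(n_days) for k in range(doses_per_day)]
    name = label or f"metronomic:{doses_per_day}x@{weekly_total:g}wk"
    return Schedule(name, _events(times, per_dose))


def weekly_total(schedule: Schedule, n_weeks: int | None = None) -> np.ndarray:
    """Total dose (mg/kg) delivered in each consecutive [7k, 7k+7) window."""
    if n_weeks is None:
        n_weeks = max(1, int(np.ceil((schedule.end + 1e-12) / 7))) if len(schedule) else 4
    totals = np.zeros(n_weeks)
    for e in schedule.events:
        week = int(e.time // 7)
        if week < n_weeks:
            totals[week] += e.amount
    return totals


_SPEC_RE = {
    "daily": re.compile(r"^daily:(?P<dose>[\d.]+)$"),
    "cycle": re.compile(r"^(?P<on>\d+)on(?P<off>\d+)off:(?P<dose>[\d.]+)$"),
    "pattern": re.compile(r"^pattern:(?P<blocks>\d+(,\d+)*)@(?P<dose>[\d.]+)$"),
    "eod": re.compile(r"^eod:(?P<dose>[\d.]+)$"),
    "metronomic": re.compile(r"^metronomic:(?P<n>\d)x@(?P<wk>[\d.]+)wk$"),
}


def parse_schedule(text: str) -> Schedule:
    """Parse the schedule mini-language used on the command line.

    Examples: ``daily:24``, ``5on2off:35``, ``pattern:4,1,1,1@42``,
    ``eod:48``, ``metronomic:3x@168wk``.
    """
    text = text.strip()
    if m := _SPEC_RE["daily"].match(text):
        return make_daily(float(m["dose"]))
    if m := _SPEC_RE["cycle"].match(text):
        return make_cycle(int(m["on"]), int(m["off"]), float(m["dose"]))
    if m := _SPEC_RE["pattern"].match(text):
        blocks = tuple(int(b) for b in m["blocks"].split(","))
        return make_weekly_pattern(blocks, float(m["dose"]))
    if m := _SPEC_RE["eod"].match(text):
        return make_every_other_day(float(m["dose"]))
    if m := _SPEC_RE["metronomic"].match(text):
        return make_metronomic(int(m["n"]), float(m["wk"]))
    raise ValueError(f"unrecognized schedule spec: {text!r}")
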