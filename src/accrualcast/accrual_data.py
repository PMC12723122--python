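"""Accrual data model: seasonal quarters, calendars, and monthly aggregation.

The time unit throughout the package is the *seasonal quarter*: a three-month
meteorological interval anchored at mid-month boundaries.  Under the default
(northern-hemisphere) calendar the quarters are

* summer: June 16 – September 15
* fall:   September 16 – December 15
* winter: December 16 – March 15
* spring: March 16 – June 15

A quarter ``j`` carries an accrual count ``m_j`` (participants enrolled), a
duration ``t_j`` expressed as a fraction of a full quarter (exposure), and a
season label ``S(j)``.  Monthly enrollment records are aggregated into these
quarters by assigning each calendar month to the quarter containing its 16th
day, so summer = {June, July, August} and so on.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Season",
    "SEASON_CYCLE",
    "SeasonCalendar",
    "METEOROLOGICAL",
    "AccrualQuarter",
    "AccrualSeries",
    "MonthlyRecord",
    "SeasonSubset",
    "assign_season",
    "quarterize",
    "season_sets",
    "season_cycle_from",
]


class Season(str, Enum):
    """One of the four seasonal quarters, in cyclic calendar order."""

    SUMMER = "summer"
    FALL = "fall"
    WINTER = "winter"
    SPRING = "spring"

    @property
    def next(self) -> "Season":
        cycle = SEASON_CYCLE
        return cycle[(cycle.index(self) + 1) % 4]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SEASON_CYCLE: tuple[Season, ...] = (
    Season.SUMMER,
    Season.FALL,
    Season.WINTER,
    Season.SPRING,
)


def season_cycle_from(start: Season, n: int) -> list[Season]:
    """Seasons of ``n`` consecutive quarters beginning with ``start``."""
    i0 = SEASON_CYCLE.index(start)
    return [SEASON_CYCLE[(i0 + i) % 4] for i in range(n)]


@dataclass(frozen=True)
class SeasonCalendar:
    """Maps (month, day) boundaries to season starts.

    ``starts`` gives, for each season, the month-day on which it begins.
    The default mid-month meteorological calendar starts each season on the
    16th; a southern-hemisphere or custom calendar may supply any four
    boundaries in increasing calendar order.
    """

    starts: Mapping[Season, tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.starts) != set(Season):
            raise ValueError("calendar must define a start for all four seasons")

    def _ordered(self) -> list[tuple[tuple[int, int], Season]]:
        return sorted(((md, s) for s, md in self.starts.items()))

    def assign(self, date: dt.date) -> Season:
        """Season whose interval contains ``date``."""
        md = (date.month, date.day)
        season = None
        for boundary, s in self._ordered():
            if md >= boundary:
                season = s
        if season is None:  # before the year's first boundary: wrap to last
            season = self._ordered()[-1][1]
        return season

    def quarter_start(self, date: dt.date) -> dt.date:
        """Start date of the quarter containing ``date``."""
        candidates = []
        for year in (date.year - 1, date.year):
            for (m, d), _ in self._ordered():
                b = dt.date(year, m, d)
                if b <= date:
                    candidates.append(b)
        return max(candidates)

    def quarter_end(self, date: dt.date) -> dt.date:
        """First day of the quarter following the one containing ``date``."""
        start = self.quarter_start(date)
        for year in (start.year, start.year + 1):
            for (m, d), _ in self._ordered():
                b = dt.date(year, m, d)
                if b > start:
                    return b
        raise AssertionError("unreachable")

    def month_season(self, year: int, month: int) -> Season:
        """Season owning a calendar month (the quarter containing its 16th)."""
        return self.assign(dt.date(year, month, 16))


METEOROLOGICAL = SeasonCalendar(
    starts={
        Season.SPRING: (3, 16),
        Season.SUMMER: (6, 16),
        Season.FALL: (9, 16),
        Season.WINTER: (12, 16),
    }
)


def assign_season(date: dt.date, calendar: SeasonCalendar = METEOROLOGICAL) -> Season:
    """Return the season containing ``date``.

    Boundaries fall on the 16th day of March/June/September/December: the
    15th belongs to the ending season, the 16th to the starting one.
    """
    return calendar.assign(date)


@dataclass(frozen=True)
class AccrualQuarter:
    """One observed quarter: count ``m_j``, exposure ``t_j``, season ``S(j)``."""

    index: int
    count: int
    duration: float
    season: Season
    start_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"quarter index must be >= 1, got {self.index}")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"count must be a non-negative integer, got {self.count}")
        if not 0 < self.duration <= 1:
            raise ValueError(
                f"duration must lie in (0, 1], got {self.duration} (quarter {self.index})"
            )


@dataclass(frozen=True)
class MonthlyRecord:
    """Enrollment count for one calendar month (``month_start`` is day 1)."""

    month_start: dt.date
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"monthly count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class AccrualSeries:
    """Chronologically ordered accrual quarters for one trial."""

    quarters: tuple[AccrualQuarter, ...]
    trial_label: str = ""
    excluded_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "quarters", tuple(self.quarters))
        for pos, q in enumerate(self.quarters, start=1):
            if q.index != pos:
                raise ValueError(
                    f"quarter indices must be 1..J without gaps; position {pos} has index {q.index}"
                )

    @property
    def J(self) -> int:
        return len(self.quarters)

    @property
    def total_count(self) -> int:
        return sum(q.count for q in self.quarters)

    @property
    def total_exposure(self) -> float:
        return sum(q.duration for q in self.quarters)

    @property
    def counts(self) -> list[int]:
        return [q.count for q in self.quarters]

    @property
    def durations(self) -> list[float]:
        return [q.duration for q in self.quarters]

    @property
    def seasons(self) -> list[Season]:
        return [q.season for q in self.quarters]

    def head(self, k: int) -> "AccrualSeries":
        """Sub-series of the first ``k`` quarters (for rolling evaluation)."""
        if not 0 <= k <= self.J:
            raise ValueError(f"k must lie in [0, {self.J}], got {k}")
        return AccrualSeries(self.quarters[:k], trial_label=self.trial_label)

    @classmethod
    def from_lists(
        cls,
        counts: Sequence[int],
        seasons: Sequence[Season],
        durations: Sequence[float] | None = None,
        trial_label: str = "",
    ) -> "AccrualSeries":
        if durations is None:
            durations = [1.0] * len(counts)
        if not len(counts) == len(seasons) == len(durations):
            raise ValueError("counts, seasons, durations must have equal length")
        quarters = tuple(
            AccrualQuarter(index=j + 1, count=int(m), duration=float(t), season=s)
            for j, (m, s, t) in enumerate(zip(counts, seasons, durations))
        )
        return cls(quarters, trial_label=trial_label)


@dataclass(frozen=True)
class SeasonSubset:
    """Per-season aggregate: total count, total exposure, member quarter indices."""

    count: int
    exposure: float
    indices: tuple[int, ...]

    @property
    def n_quarters(self) -> int:
        return len(self.indices)


def season_sets(series: AccrualSeries) -> dict[Season, SeasonSubset]:
    """Partition a series by season: J_s = {j : S(j) = s} with totals.

    The four subsets partition 1..J exactly: per-season counts sum to the
    series total and per-season exposures sum to sum(t_j).
    """
    out: dict[Season, SeasonSubset] = {}
    for s in SEASON_CYCLE:
        members = [q for q in series.quarters if q.season is s]
        out[s] = SeasonSubset(
            count=sum(q.count for q in members),
            exposure=sum(q.duration for q in members),
            indices=tuple(q.index for q in members),
        )
    return out


def _next_month(d: dt.date) -> dt.date:
    return dt.date(d.year + (d.month == 12), d.month % 12 + 1, 1)


def quarterize(
    monthly: Iterable[MonthlyRecord],
    trial_start: dt.date | None = None,
    *,
    drop_partial_first: bool = False,
    partial_threshold: float = 0.5,
    full_first_quarter: bool = True,
    calendar: SeasonCalendar = METEOROLOGICAL,
    trial_label: str = "",
) -> AccrualSeries:
    """Aggregate contiguous monthly records into seasonal quarters.

    Each month joins the quarter containing its 16th day.  The first
    quarter's day-exact duration is (days from ``trial_start`` to the
    quarter boundary) / (days in the quarter); with ``full_first_quarter``
    (the default) it is recorded as 1 instead.  If ``drop_partial_first`` is
    set and the day-exact first-quarter coverage falls below
    ``partial_threshold``, the first quarter is removed and its count
    reported on the returned series as ``excluded_count``.  A trailing
    quarter with fewer than three months gets duration months/3.

    Raises ``ValueError`` on empty input or a gap in the monthly sequence.
    """
    records = sorted(monthly, key=lambda r: r.month_start)
    if not records:
        raise ValueError("no monthly records supplied")
    for r in records:
        if r.month_start.day != 1:
            raise ValueError(f"month_start must be the first of a month: {r.month_start}")
    for prev, cur in zip(records, records[1:]):
        expected = _next_month(prev.month_start)
        if cur.month_start != expected:
            raise ValueError(
                f"monthly records have a gap: {prev.month_start:%Y-%m} is followed by "
                f"{cur.month_start:%Y-%m} (expected {expected:%Y-%m})"
            )
    if trial_start is None:
        trial_start = records[0].month_start
    first = records[0].month_start
    if not (first <= trial_start < _next_month(first)):
        raise ValueError(
            f"trial_start {trial_start} does not fall within the first month {first:%Y-%m}"
        )

    # group months by the start date of their owning quarter
    groups: list[tuple[dt.date, list[MonthlyRecord]]] = []
    for r in records:
        qstart = calendar.quarter_start(dt.date(r.month_start.year, r.month_start.month, 16))
        if groups and groups[-1][0] == qstart:
            groups[-1][1].append(r)
        else:
            groups.append((qstart, [r]))

    quarters: list[AccrualQuarter] = []
    excluded = 0
    for gi, (qstart, members) in enumerate(groups):
        season = calendar.assign(qstart)
        count = sum(r.count for r in members)
        qend = calendar.quarter_end(qstart)
        if gi == 0:
            span = (qend - qstart).days
            covered = (qend - max(trial_start, qstart)).days
            frac = covered / span
            if drop_partial_first and frac < partial_threshold:
                excluded = count
                continue
            duration = 1.0 if full_first_quarter else frac
            start = max(trial_start, qstart)
        elif gi == len(groups) - 1 and len(members) < 3:
            duration = len(members) / 3
            start = qstart
        else:
            duration = 1.0
            start = qstart
        quarters.append(
            AccrualQuarter(
                index=len(quarters) + 1,
                count=count,
                duration=duration,
                season=season,
                start_date=start,
            )
        )
    if not quarters:
        raise ValueError("all quarters were excluded as partial; nothing to model")
    return AccrualSeries(tuple(quarters), trial_label=trial_label, excluded_count=excluded)
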