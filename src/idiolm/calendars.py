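"""Academic-year study calendar: two semesters bridged by a winter break.

The cohort design spans a fall semester and a spring semester (roughly 16
weeks each) separated by a class-free winter break (roughly 5 weeks).
Weekdays are ordered Saturday through Friday, matching the convention that a
daily observation starts with the nighttime sleep episode (so weekend
mornings lead the week).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

WEEKDAY_ORDER: tuple[str, ...] = (
    "Saturday",
    "Sunday",
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
)

#: default maximum number of in-semester days (fall + spring)
DEFAULT_MAX_SEMESTER_DAYS = 223


def weekday_index(d: date) -> int:
    """Index of ``d`` in the Saturday-first weekday ordering (0..6)."""
    # datetime.weekday(): Monday=0 ... Sunday=6; shift so Saturday=0
    return (d.weekday() + 2) % 7


def weekday_label(d: date) -> str:
    return WEEKDAY_ORDER[weekday_index(d)]


@dataclass(frozen=True)
class StudyCalendar:
    """Contiguous fall-semester / winter-break / spring-semester date ranges.

    All ranges are inclusive of both endpoints.  A zero-length break is
    represented by ``break_end == break_start - 1 day`` (an empty range at
    the fall/spring boundary).
    """

    fall_start: date
    fall_end: date
    break_start: date
    break_end: date
    spring_start: date
    spring_end: date

    def __post_init__(self) -> None:
        if not (self.fall_start <= self.fall_end):
            raise ValueError("fall semester must span at least one day")
        if not (self.spring_start <= self.spring_end):
            raise ValueError("spring semester must span at least one day")
        if not (self.fall_end < self.break_start):
            raise ValueError("break must start after the fall semester ends")
        if self.break_end < self.break_start - timedelta(days=1):
            raise ValueError("malformed break range")
        if not (self.break_end < self.spring_start):
            raise ValueError("spring must start after the break ends")

    # -- range queries ---------------------------------------------------
    def in_break(self, d: date) -> bool:
        return self.break_start <= d <= self.break_end

    def in_fall(self, d: date) -> bool:
        return self.fall_start <= d <= self.fall_end

    def in_spring(self, d: date) -> bool:
        return self.spring_start <= d <= self.spring_end

    def in_semester(self, d: date) -> bool:
        return self.in_fall(d) or self.in_spring(d)

    def in_study(self, d: date) -> bool:
        return self.fall_start <= d <= self.spring_end

    def period(self, d: date) -> str:
        """One of 'fall', 'break', 'spring'; raises for out-of-study dates."""
        if self.in_fall(d):
            return "fall"
        if self.in_break(d):
            return "break"
        if self.in_spring(d):
            return "spring"
        raise ValueError(f"{d} is outside the study calendar")

    # -- day enumerations ------------------------------------------------
    def all_days(self) -> list[date]:
        """Every calendar day from fall_start to spring_end inclusive."""
        n = (self.spring_end - self.fall_start).days + 1
        return [self.fall_start + timedelta(days=i) for i in range(n)]

    def semester_days(self) -> list[date]:
        return [d for d in self.all_days() if self.in_semester(d)]

    def break_days(self) -> list[date]:
        return [d for d in self.all_days() if self.in_break(d)]

    @property
    def n_semester_days(self) -> int:
        fall = (self.fall_end - self.fall_start).days + 1
        spring = (self.spring_end - self.spring_start).days + 1
        return fall + spring


def make_calendar(
    fall_start: date,
    semester_weeks: int = 16,
    break_weeks: int = 5,
    max_semester_days: int | None = None,
) -> StudyCalendar:
    """Build a contiguous fall / break / spring calendar.

    Parameters
    ----------
    fall_start
        First day of the fall semester.
    semester_weeks
        Length of each semester, in whole weeks (>= 1).
    break_weeks
        Length of the winter break, in whole weeks (>= 0).
    max_semester_days
        If given, trim trailing spring days so that the total number of
        in-semester days does not exceed this cap.
    """
    if semester_weeks < 1:
        raise ValueError("semester_weeks must be >= 1")
    if break_weeks < 0:
        raise ValueError("break_weeks must be >= 0")
    sem = 7 * semester_weeks
    brk = 7 * break_weeks
    fall_end = fall_start + timedelta(days=sem - 1)
    break_start = fall_end + timedelta(days=1)
    break_end = break_start + timedelta(days=brk - 1)  # empty range if brk == 0
    spring_start = break_end + timedelta(days=1)
    spring_end = spring_start + timedelta(days=sem - 1)
    if max_semester_days is not None:
        excess = 2 * sem - max_semester_days
        if excess >= sem:
            raise ValueError("max_semester_days would remove the whole spring semester")
        if excess > 0:
            spring_end -= timedelta(days=excess)
    return StudyCalendar(
        fall_start=fall_start,
        fall_end=fall_end,
        break_start=break_start,
        break_end=break_end,
        spring_start=spring_start,
        spring_end=spring_end,
    )


def default_calendar() -> StudyCalendar:
    """The default academic year: 16-week semesters, 5-week break, 223 days.

    Starts on Monday 2017-09-04; two 112-day semesters are trimmed by one
    trailing spring day to the 223 in-semester days a participant could at
    most contribute.
    """
    return make_calendar(
        date(2017, 9, 4),
        semester_weeks=16,
        break_weeks=5,
        max_semester_days=DEFAULT_MAX_SEMESTER_DAYS,
    )
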