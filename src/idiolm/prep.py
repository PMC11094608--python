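"""Daily-record ingestion, inclusion filters, and per-person model designs.

A daily observation on day *t* starts with the nighttime sleep episode
ending that morning and ends with the evening survey submitted on day *t*.
Preparation applies, in order: the on-time survey window (17:00 to 06:00
the following day), the minimum-compliance inclusion rule (at least 100
on-time surveys), and the winter-break exclusion.  From the filtered series
it builds the design for one of four model presets, each regressing nightly
sleep duration (minutes) or using it to back-predict a Likert report:

========================  ==================  =========  =====
preset                    predictor           lag        notes
========================  ==================  =========  =====
``quality_concurrent``    sleep quality       0          proof-of-concept
``quality_lag1``          sleep quality       1          sleep-rebound probe
``stress_day_before``     stress              1          stress -> sleep
``stress_day_after``      stress              0          sleep -> stress
                                                         (back-prediction)
========================  ==================  =========  =====

Lag-1 pairs require strict calendar adjacency: day *t-1* must be the
immediately preceding date, so gaps and the winter break never get bridged
into a one-day lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from .calendars import WEEKDAY_ORDER, StudyCalendar, weekday_index
from .simulate import RECORD_COLUMNS

__all__ = [
    "ModelSpec",
    "ModelData",
    "PRESETS",
    "ValidationError",
    "InsufficientDataError",
    "read_daily_csv",
    "filter_on_time_surveys",
    "apply_inclusion",
    "exclude_break",
    "build_model_data",
]

SURVEY_FIELDS = ["sleep_quality", "stress", "survey_submit_time"]

DEFAULT_MIN_SURVEYS = 100
MIN_MODEL_OBS = 10


class ValidationError(ValueError):
    """Malformed or out-of-range input data."""


class InsufficientDataError(ValueError):
    """Too few complete observations to fit a model."""


@dataclass(frozen=True)
class ModelSpec:
    """One of the four preset person-level regressions."""

    name: str
    outcome: str  # always sleep_duration_min
    predictor: str  # sleep_quality or stress
    predictor_lag: int  # 0 or 1

    def __post_init__(self) -> None:
        if self.predictor_lag not in (0, 1):
            raise ValueError("predictor_lag must be 0 or 1")


PRESETS: dict[str, ModelSpec] = {
    "quality_concurrent": ModelSpec(
        "quality_concurrent", "sleep_duration_min", "sleep_quality", 0
    ),
    "quality_lag1": ModelSpec("quality_lag1", "sleep_duration_min", "sleep_quality", 1),
    "stress_day_before": ModelSpec(
        "stress_day_before", "sleep_duration_min", "stress", 1
    ),
    "stress_day_after": ModelSpec("stress_day_after", "sleep_duration_min", "stress", 0),
}


@dataclass
class ModelData:
    """Design package for one person-level fit.

    ``weekday`` holds Saturday-first weekday indices (0..6) of the date the
    outcome (sleep episode) was acquired.
    """

    participant_id: str
    spec: ModelSpec
    y: np.ndarray  # minutes
    x: np.ndarray  # Likert values
    weekday: np.ndarray  # intp, 0..6
    dates: np.ndarray  # datetime64[D] of the outcome day

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def sd_y(self) -> float:
        return float(np.std(self.y, ddof=1))

    @property
    def sd_x(self) -> float:
        return float(np.std(self.x, ddof=1))

    def design_matrix(self, reference: int = 0) -> np.ndarray:
        """n x 8 design: intercept, predictor, six weekday dummies.

        ``reference`` is the weekday index (Saturday-first) absorbed into
        the intercept; the slope on the predictor is invariant to it.
        """
        dummies = np.zeros((self.n, 6))
        others = [k for k in range(7) if k != reference]
        for j, k in enumerate(others):
            dummies[:, j] = self.weekday == k
        return np.column_stack([np.ones(self.n), self.x, dummies])

    def feature_names(self, reference: int = 0) -> list[str]:
        others = [k for k in range(7) if k != reference]
        return (
            ["intercept", "slope"] + [f"wd_{WEEKDAY_ORDER[k]}" for k in others]
        )


# ---------------------------------------------------------------------------
# ingestion


def read_daily_csv(path) -> list[pd.DataFrame]:
    """Read a long-format daily-record CSV into per-participant series.

    Validates the schema and value ranges, rejects duplicate
    (participant, date) rows, and returns one date-sorted DataFrame per
    participant (participants in order of first appearance).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    issues = validate_records(df)
    errors = [i for i in issues if i["severity"] == "error"]
    if errors:
        first = errors[0]
        raise ValidationError(
            f"{len(errors)} invalid rows; first: line {first['line']}: {first['message']}"
        )
    df = _coerce_types(df)
    out = []
    for pid in df["participant_id"].unique():
        sub = df[df["participant_id"] == pid].sort_values("date").reset_index(drop=True)
        out.append(sub)
    return out


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    df["survey_submit_time"] = pd.to_datetime(df["survey_submit_time"])
    for c in ("sleep_duration_min", "sleep_quality", "stress"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    df["actigraphy_usable"] = df["actigraphy_usable"].astype(int)
    return df


def validate_records(df: pd.DataFrame) -> list[dict]:
    """Schema/range/duplicate checks; returns one dict per issue.

    Line numbers are 1-based and count the header, matching what an editor
    shows for the CSV file.
    """
    issues: list[dict] = []

    def add(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask.fillna(False).astype(bool)]:
            issues.append(
                {"line": int(idx) + 2, "severity": "error", "message": message}
            )

    try:
        dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    except Exception:
        dates = pd.Series(pd.NaT, index=df.index)
    add(dates.isna(), "unparseable date")

    for col, lo, hi, integral in [
        ("sleep_duration_min", 0.0, 1440.0, False),
        ("sleep_quality", 1, 5, True),
        ("stress", 1, 5, True),
    ]:
        v = pd.to_numeric(df[col], errors="coerce")
        bad_parse = v.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        add(bad_parse, f"unparseable {col}")
        present = v.notna()
        if integral:
            add(present & (v != v.round()), f"{col} must be an integer")
            add(present & ((v < lo) | (v > hi)), f"{col} out of range [{lo}, {hi}]")
        else:
            add(present & ((v < lo) | (v >= hi)), f"{col} out of range [0, 1440)")

    dup = df.duplicated(subset=["participant_id", "date"], keep=False) & ~df.duplicated(
        subset=["participant_id", "date"], keep="first"
    )
    add(dup, "duplicate participant-day")
    return issues


# ---------------------------------------------------------------------------
# the three filters


def filter_on_time_surveys(
    series: pd.DataFrame,
    window_open: time = time(17, 0),
    window_close_next_day: time = time(6, 0),
) -> pd.DataFrame:
    """Blank survey fields on days whose survey was late or untimestamped.

    A survey is on time when submitted between ``window_open`` on the
    survey day and ``window_close_next_day`` the following day, both
    boundaries inclusive.  Sleep fields are untouched; the filter is
    idempotent.
    """
    out = series.copy()
    submit = out["survey_submit_time"]
    day = out["date"].dt.normalize()
    open_dt = day + pd.Timedelta(hours=window_open.hour, minutes=window_open.minute)
    close_dt = (
        day
        + pd.Timedelta(days=1)
        + pd.Timedelta(hours=window_close_next_day.hour, minutes=window_close_next_day.minute)
    )
    has_survey = out[["sleep_quality", "stress"]].notna().any(axis=1) | submit.notna()
    on_time = submit.notna() & (submit >= open_dt) & (submit <= close_dt)
    drop = has_survey & ~on_time
    out.loc[drop, "sleep_quality"] = np.nan
    out.loc[drop, "stress"] = np.nan
    out.loc[drop, "survey_submit_time"] = pd.NaT
    return out


def count_usable_surveys(series: pd.DataFrame) -> int:
    """Days with a retained (on-time) survey, i.e. a present stress rating."""
    return int(series["stress"].notna().sum())


def apply_inclusion(series: pd.DataFrame, min_surveys: int = DEFAULT_MIN_SURVEYS) -> bool:
    """Compliance rule: include iff at least ``min_surveys`` on-time surveys.

    Expects the on-time filter to have been applied already.
    """
    return count_usable_surveys(series) >= min_surveys


def exclude_break(series: pd.DataFrame, calendar: StudyCalendar) -> pd.DataFrame:
    """Keep only records dated within the two school semesters.

    Winter-break days are excluded inclusively on both boundary days, and
    records outside the study calendar entirely are dropped too.
    """
    dates = series["date"].dt.date
    keep = dates.map(calendar.in_semester)
    return series[keep.to_numpy(bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# design construction


def build_model_data(
    series: pd.DataFrame,
    spec: ModelSpec,
    calendar: StudyCalendar | None = None,
    min_obs: int = MIN_MODEL_OBS,
) -> ModelData:
    """Assemble the regression design for one participant and preset.

    Lag-0 presets keep days with both the outcome and the predictor present;
    lag-1 presets keep days *t* whose outcome is present and whose predictor
    on the immediately preceding calendar date is present (gaps and the
    winter break are never bridged).  Sleep duration counts as present only
    on actigraphy-usable days.
    """
    s = series
    if calendar is not None:
        s = exclude_break(s, calendar)
    s = s.sort_values("date").reset_index(drop=True)

    y_ok = s["sleep_duration_min"].notna() & (s["actigraphy_usable"] == 1)
    x_all = s[spec.predictor]

    if spec.predictor_lag == 0:
        keep = (y_ok & x_all.notna()).to_numpy()
        x = x_all.to_numpy(float)[keep]
        out_rows = s[keep]
    else:
        prev_date = s["date"].shift(1)
        adjacent = (s["date"] - prev_date) == pd.Timedelta(days=1)
        x_prev = x_all.shift(1)
        keep = (y_ok & adjacent.fillna(False) & x_prev.notna()).to_numpy()
        x = x_prev.to_numpy(float)[keep]
        out_rows = s[keep]

    y = out_rows["sleep_duration_min"].to_numpy(float)
    dates = out_rows["date"].dt.date
    weekday = np.fromiter((weekday_index(d) for d in dates), dtype=np.intp, count=len(y))
    pid = str(series["participant_id"].iloc[0]) if len(series) else "?"
    if len(y) < min_obs:
        raise InsufficientDataError(
            f"participant {pid}, preset {spec.name}: only {len(y)} usable "
            f"observations (minimum {min_obs})"
        )
    return ModelData(
        participant_id=pid,
        spec=spec,
        y=y,
        x=x,
        weekday=weekday,
        dates=out_rows["date"].to_numpy(dtype="datetime64[D]"),
    )
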